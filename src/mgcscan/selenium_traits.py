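"""Selenium-utilization trait profiling and MGC co-occurrence.

Genomes are scanned for the selenocysteine machinery (selA: l-seryl-tRNA
selenium transferase, selB: Sec-specific elongation factor, selD:
selenide-water dikinase) and for glycine reductase, and classified:

* ``full_machinery`` — selA and selB and selD present;
* ``selD_only``      — selD present but not (selA and selB); such
  organisms use the selenium cofactor without making selenocysteine;
* ``none``           — no selD.

selC (tRNA-Sec) cannot be detected from protein seeds; when RNA
annotations are available its presence is taken from a product-text
match, otherwise it is reported but never used for classification.

The co-occurrence statistic is the fraction of MGC-positive genomes
whose classification shows any selenium trait (configurable to
full-machinery only).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homology import RoleAssignment


@dataclass(frozen=True)
class SeleniumTraitProfile:
    genome_id: str
    has_selA: bool
    has_selB: bool
    has_selC: bool
    has_selD: bool
    has_glycine_reductase: bool
    classification: str  # full_machinery | selD_only | none


def classify_traits(has_selA: bool, has_selB: bool, has_selD: bool) -> str:
    """Total classification of the trait booleans (selC never keys it)."""
    if has_selA and has_selB and has_selD:
        return "full_machinery"
    if has_selD:
        return "selD_only"
    return "none"


def scan_traits(genome, roles) -> SeleniumTraitProfile:
    """Profile one genome from its role assignments.

    ``roles`` maps feature_id to a role name or RoleAssignment; booleans
    record presence anywhere in the genome.
    """
    role_names = {
        fid: (r.role if isinstance(r, RoleAssignment) else r)
        for fid, r in roles.items()
    }
    present = set(role_names.values())
    has_selC = any(
        f.feature_type in ("tRNA",) and "sec" in f.product.lower()
        for f in genome.features()
    ) or "SelC" in present
    return SeleniumTraitProfile(
        genome_id=genome.genome_id,
        has_selA="SelA" in present,
        has_selB="SelB" in present,
        has_selC=has_selC,
        has_selD="SelD" in present,
        has_glycine_reductase="GlyReductase" in present,
        classification=classify_traits(
            "SelA" in present, "SelB" in present, "SelD" in present
        ),
    )


def cooccurrence_fraction(
    profiles: list[SeleniumTraitProfile],
    mgc_positive_genomes: set[str],
    full_machinery_only: bool = False,
) -> float:
    """Fraction of MGC-positive genomes carrying selenium traits.

    By default any selenium trait (classification != none) counts;
    ``full_machinery_only`` restricts to complete selABD machinery.
    """
    if not mgc_positive_genomes:
        raise ValueError("cooccurrence_fraction: empty MGC-positive set")
    by_id = {p.genome_id: p for p in profiles}
    missing = mgc_positive_genomes - set(by_id)
    if missing:
        raise ValueError(
            f"cooccurrence_fraction: no profile for genomes {sorted(missing)}"
        )
    if full_machinery_only:
        hits = sum(
            by_id[g].classification == "full_machinery" for g in mgc_positive_genomes
        )
    else:
        hits = sum(
            by_id[g].classification != "none" for g in mgc_positive_genomes
        )
    return hits / len(mgc_positive_genomes)


def classify_mgc_selenium_context(candidate, profile: SeleniumTraitProfile) -> str:
    """selenium_associated iff the host genome shows any selenium trait."""
    if candidate.genome_id != profile.genome_id:
        raise ValueError(
            "candidate and profile belong to different genomes "
            f"({candidate.genome_id} vs {profile.genome_id})"
        )
    return "selenium_associated" if profile.classification != "none" else "non_selenium"


def profiles_to_table(profiles: list[SeleniumTraitProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": p.genome_id,
                "selA": p.has_selA,
                "selB": p.has_selB,
                "selC": p.has_selC,
                "selD": p.has_selD,
                "glycine_reductase": p.has_glycine_reductase,
                "classification": p.classification,
            }
            for p in profiles
        ],
        columns=["genome_id", "selA", "selB", "selC", "selD",
                 "glycine_reductase", "classification"],
    )
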
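"""Methyltransferase assay analysis and substrate-inhibition kinetics.

The steady-state model is the standard uncompetitive substrate-inhibition
form

    v / E0 = kcat * S / (KM + S + S**2 / KI)

with kcat in 1/min, KM and KI in uM.  The rate is 0 at S = 0 and maximal
at S = sqrt(KM * KI); as KI -> inf it reduces uniformly to
Michaelis-Menten on any bounded substrate interval.

Fitting follows a Model/Results pattern: build a
:class:`SubstrateInhibitionModel` from a dataset (or DataFrame), call
``fit()``, and read estimates, standard errors, diagnostics and
``summary()`` off the returned :class:`KineticsResults`.  The objective
is (optionally weighted) nonlinear least squares in log-parameter space,
which enforces positivity and tames the mild ill-conditioning that
appears when KI is far above the sampled substrate range; seeded
multi-start guards against local minima.

Absorbance traces (A525 = methylcob(III)alamin band; A485 = the
methylcob(III)alamin/cob(II)alamin isosbestic point) yield initial rates
by ordinary least squares over a time window, fold-changes against
controls, and an isosbestic drift QC statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


def substrate_inhibition_rate(S, kcat: float, KM: float, KI: float):
    """Turnover v/E0 (1/min) at substrate concentration S (uM)."""
    if kcat <= 0 or KM <= 0 or KI <= 0:
        raise ValueError("kinetic parameters must be positive")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentrations must be >= 0")
    v = kcat * S / (KM + S + S**2 / KI)
    return float(v) if v.ndim == 0 else v


def michaelis_menten_rate(S, kcat: float, KM: float):
    S = np.asarray(S, dtype=float)
    v = kcat * S / (KM + S)
    return float(v) if v.ndim == 0 else v


def optimal_substrate(KM: float, KI: float) -> float:
    """Substrate concentration maximising the substrate-inhibition rate."""
    return math.sqrt(KM * KI)


@dataclass
class AbsorbanceTrace:
    """A time course of the 525 nm band, optionally with the 485 nm channel."""

    time_min: np.ndarray
    a525: np.ndarray
    a485: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.a525 = np.asarray(self.a525, dtype=float)
        if self.a485 is not None:
            self.a485 = np.asarray(self.a485, dtype=float)
            if len(self.a485) != len(self.time_min):
                raise ValueError("a485 length mismatch")
        if len(self.time_min) != len(self.a525):
            raise ValueError("time and a525 length mismatch")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class KineticDataset:
    """Initial-rate data: v/E0 (1/min) per substrate concentration (uM)."""

    substrate_uM: np.ndarray
    rate_per_min: np.ndarray
    replicate_id: np.ndarray | None = None
    enzyme_uM: float | None = None

    def __post_init__(self) -> None:
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.rate_per_min = np.asarray(self.rate_per_min, dtype=float)
        if len(self.substrate_uM) != len(self.rate_per_min):
            raise ValueError("substrate and rate length mismatch")
        if np.any(self.substrate_uM < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(len(self.substrate_uM), dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id)
            if len(self.replicate_id) != len(self.substrate_uM):
                raise ValueError("replicate_id length mismatch")

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.substrate_uM))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, enzyme_uM: float | None = None):
        return cls(
            substrate_uM=df["substrate_uM"].to_numpy(),
            rate_per_min=df["rate"].to_numpy(),
            replicate_id=(
                df["replicate"].to_numpy() if "replicate" in df.columns else None
            ),
            enzyme_uM=enzyme_uM,
        )

    @classmethod
    def from_csv(cls, path, enzyme_uM: float | None = None):
        return cls.from_dataframe(pd.read_csv(path), enzyme_uM=enzyme_uM)


PARAM_NAMES = ("kcat", "KM", "KI")


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class SubstrateInhibitionModel:
    """Nonlinear least-squares model for substrate-inhibition kinetics.

    Parameters
    ----------
    data : KineticDataset or pandas.DataFrame with columns
        ``substrate_uM``, ``rate`` (and optional ``replicate``).
    weighting : ``None`` (unweighted, default) or ``"proportional"``
        (residuals divided by the model value, appropriate for
        constant-CV noise).
    """

    def __init__(self, data, weighting: str | None = None):
        if isinstance(data, pd.DataFrame):
            data = KineticDataset.from_dataframe(data)
        self.data = data
        if weighting not in (None, "proportional"):
            raise ValueError("weighting must be None or 'proportional'")
        self.weighting = weighting
        if data.n_levels < 5:
            raise ValueError(
                "need >=5 distinct substrate levels for a 3-parameter fit "
                f"(got {data.n_levels})"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "SubstrateInhibitionModel":
        return cls(df, **kw)

    def default_init(self) -> np.ndarray:
        """Heuristic start: kcat from the peak, KM from the rising limb,
        KI well above the sampled range."""
        S, v = self.data.substrate_uM, self.data.rate_per_min
        vmax = float(np.max(v))
        kcat0 = 1.2 * vmax if vmax > 0 else 1.0
        rising = S[(v >= 0.5 * vmax) & (S <= S[np.argmax(v)])]
        KM0 = float(np.min(rising)) if len(rising) else float(np.median(S[S > 0]))
        KM0 = max(KM0, 1e-6)
        KI0 = 10.0 * float(np.max(S))
        return np.array([kcat0, KM0, KI0])

    def _residuals(self, log_params: np.ndarray) -> np.ndarray:
        kcat, KM, KI = np.exp(log_params)
        pred = kcat * self.data.substrate_uM / (
            KM + self.data.substrate_uM + self.data.substrate_uM**2 / KI
        )
        res = pred - self.data.rate_per_min
        if self.weighting == "proportional":
            res = res / np.maximum(np.abs(pred), 1e-12)
        return res

    def fit(
        self,
        init: tuple[float, float, float] | None = None,
        restarts: int = 10,
        seed: int = 0,
    ) -> "KineticsResults":
        """Fit by multi-start nonlinear least squares.

        ``restarts`` additional starts perturb the initial guess
        multiplicatively (seeded); the best converged solution wins.
        Raises :class:`ConvergenceError` (carrying the best attempt) when
        nothing converges.
        """
        x0 = np.log(np.asarray(init if init is not None else self.default_init(),
                               dtype=float))
        rng = np.random.default_rng(seed)
        starts = [x0] + [
            x0 + rng.normal(0.0, 0.7, size=3) for _ in range(restarts)
        ]
        best = None
        for start in starts:
            try:
                sol = optimize.least_squares(
                    self._residuals, start, method="lm", max_nfev=10000
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise ConvergenceError("substrate-inhibition fit did not converge",
                                   best_attempt=best)
        return KineticsResults(self, best)


@dataclass
class KineticsResults:
    """Estimates, uncertainties and diagnostics of a substrate-inhibition fit."""

    model: SubstrateInhibitionModel
    _solution: object
    params: dict[str, float] = field(init=False)
    bse: dict[str, float] = field(init=False)
    rss: float = field(init=False)
    flags: set[str] = field(init=False)

    def __post_init__(self) -> None:
        log_theta = self._solution.x
        theta = np.exp(log_theta)
        res = self._solution.fun
        n, p = len(res), 3
        self.rss = float(res @ res)
        # covariance via the Jacobian in log space, delta method back
        J = self._solution.jac
        dof = max(n - p, 1)
        s2 = self.rss / dof
        try:
            cov_log = s2 * np.linalg.inv(J.T @ J)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
            se = theta * se_log  # d exp(x) = exp(x) dx
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        self.params = dict(zip(PARAM_NAMES, map(float, theta)))
        self.bse = dict(zip(PARAM_NAMES, map(float, se)))
        self.flags = set()
        max_S = float(np.max(self.model.data.substrate_uM))
        if self.params["KI"] > 100.0 * max_S:
            self.flags.add("no_inhibition_detected")
        if np.any(theta < 1e-10) or self.params["KI"] > 1e12:
            self.flags.add("boundary_hit")

    @property
    def kcat(self) -> float:
        return self.params["kcat"]

    @property
    def KM(self) -> float:
        return self.params["KM"]

    @property
    def KI(self) -> float:
        return self.params["KI"]

    @property
    def nobs(self) -> int:
        return len(self.model.data.substrate_uM)

    def predict(self, S) -> np.ndarray:
        return substrate_inhibition_rate(S, self.kcat, self.KM, self.KI)

    def optimal_substrate(self) -> float:
        return optimal_substrate(self.KM, self.KI)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, df=max(self.nobs - 3, 1))
        rows = {
            name: (self.params[name] - q * self.bse[name],
                   self.params[name] + q * self.bse[name])
            for name in PARAM_NAMES
        }
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def summary(self) -> str:
        units = {"kcat": "1/min", "KM": "uM", "KI": "uM"}
        lines = [
            "Substrate-inhibition kinetics fit",
            "  model: v/E0 = kcat*S / (KM + S + S^2/KI)",
            f"  n obs: {self.nobs}   distinct S levels: {self.model.data.n_levels}",
            f"  RSS:   {self.rss:.6g}",
            "",
            f"  {'param':<6} {'estimate':>12} {'std err':>12}  unit",
        ]
        for name in PARAM_NAMES:
            lines.append(
                f"  {name:<6} {self.params[name]:>12.4g} "
                f"{self.bse[name]:>12.3g}  {units[name]}"
            )
        lines.append(
            f"  rate maximum at S = sqrt(KM*KI) = {self.optimal_substrate():.4g} uM"
        )
        if self.flags:
            lines.append(f"  flags: {', '.join(sorted(self.flags))}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "standard_errors": self.bse,
            "rss": self.rss,
            "flags": sorted(self.flags),
            "n_obs": self.nobs,
        }


def fit_substrate_inhibition(
    dataset, init=None, weighting=None, restarts: int = 10, seed: int = 0
) -> KineticsResults:
    """Functional wrapper around :class:`SubstrateInhibitionModel`."""
    return SubstrateInhibitionModel(dataset, weighting=weighting).fit(
        init=init, restarts=restarts, seed=seed
    )


def initial_rate(
    trace: AbsorbanceTrace, window_minutes: tuple[float, float]
) -> tuple[float, float]:
    """OLS slope (AU/min) of A525 vs time over the window, with its SE."""
    lo, hi = window_minutes
    mask = (trace.time_min >= lo) & (trace.time_min <= hi)
    if mask.sum() < 5:
        raise ValueError(
            f"initial_rate: fewer than 5 points in window [{lo}, {hi}] min"
        )
    fit = stats.linregress(trace.time_min[mask], trace.a525[mask])
    return float(fit.slope), float(fit.stderr)


def fold_change_slower(rate_test: float, rate_control: float) -> float:
    """Fold by which the control trace is slower than the full reaction.

    Signs are ignored (the band is disappearing, so rates are negative);
    a zero control rate flags an infinite fold-change.
    """
    if rate_control == 0:
        return math.inf
    return abs(rate_test) / abs(rate_control)


def isosbestic_drift(trace: AbsorbanceTrace) -> float:
    """Max |deltaA485| from the initial value; QC for clean two-state conversion."""
    if trace.a485 is None:
        raise ValueError("isosbestic_drift: trace has no 485 nm channel")
    return float(np.max(np.abs(trace.a485 - trace.a485[0])))


def read_trace_csv(path) -> AbsorbanceTrace:
    """CSV columns: time_min, a525 [, a485]."""
    df = pd.read_csv(path)
    return AbsorbanceTrace(
        time_min=df["time_min"].to_numpy(),
        a525=df["a525"].to_numpy(),
        a485=df["a485"].to_numpy() if "a485" in df.columns else None,
    )
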
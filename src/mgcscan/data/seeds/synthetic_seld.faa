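>seed_selD synthetic seed protein, role SelD
HIWDQWHSGDHTHWRIHNYWMPWPVHHCFCKFAARFRPQRVKHSGLAPDISTDKRPGIYH
PIRVAHHGYCNRQVDCWATIRNRAREYGQASHVEFVVHQVMQGWRYGHSLSGDCCYSANQ
QMPQEEAENYYVRNSHSASCIKFGGAERFRVVNAGVLFSPEMFNCINYFSRTHKNMQSWD
KLPVKDGPAHHKRHQPNYKMTPQQTETHRSWSDKTAPEWCICDDVYPIAMCEYLEICNDK
KWKKCLPICHHPRKLWHCPRSSIKRPVARMKYTGFNAMCRMGFGCPFFHVIDWCQVFASL
VEAMQHMTHQQWDHFPHGWWMQKMEGYRGIWYEEIKFTQA
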
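# Synthetic MRSA teicoplanin MIC histogram (editable fixture).
# This is NOT surveillance data: it is a plausible stand-in shaped like
# EUCAST-style MRSA distributions (most isolates at 0.5-1 mg/L). Replace
# this file with a current surveillance snapshot for real CFR estimates.
# columns: MIC (mg/L)  fraction of isolates
0.25    0.10
0.5     0.55
1       0.30
2       0.04
4       0.01
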
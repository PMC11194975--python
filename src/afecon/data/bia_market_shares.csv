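year,warfarin,apixaban,rivaroxaban,lmwh
2024,0.21,0.29,0.38,0.12
2025,0.20,0.30,0.39,0.12
2026,0.18,0.30,0.40,0.11
2027,0.18,0.31,0.40,0.11
2028,0.17,0.32,0.40,0.11
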
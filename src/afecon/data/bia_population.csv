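year,national_population,eligible_patients
2024,86369815,30471
2025,87406253,30837
2026,88455128,31207
2027,89516589,31581
2028,90590788,31960
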
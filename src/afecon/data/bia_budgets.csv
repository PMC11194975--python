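year,scenario1,scenario2,scenario3,impact_1_2,impact_1_3
2024,76663950,70250296,77779016,-6413654,-7528720
2025,78014031,71299598,79119164,-6714432,-7819566
2026,76681764,69886759,78003068,-6795005,-8116309
2027,78431527,71325764,79539468,-7105764,-8213704
2028,79193663,71770662,80082930,-7423002,-8312269
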
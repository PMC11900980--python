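{
 "de_mirnas_synthetic.csv": "cbd26f8557e7632be37d9eabca7f6024cff0bbd9cc43ebb8905f65ff16eec62c",
 "known_pairs.csv": "91b283c64422e842891f6027b94f5205810ab21816b2359667667d984f5ce076",
 "table1_interactions.csv": "9dc2551b53d694cd572d9c9c7c58e60e8ba30a53536a48b5f1032d131fb6697b",
 "table2_regulators.csv": "e0fe1156b9c45317950e697cd0997a95ed5cc16bf8de17399deec2a1635a06c1"
}
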
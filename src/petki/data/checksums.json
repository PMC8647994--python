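{
 "table1_group2.csv": "fb185bfdc920e3e73869cd8180a016cb7a403ca6f4e00dae648bbfb1d12643de",
 "table2_group3.csv": "5b7de6fba43e1c027890cced3785125461e58f4823c3c78967313e68cb93e655"
}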
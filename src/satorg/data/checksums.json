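{
  "table1.tsv": "65c1f8e914f44e0c84212383f5f1877ee06fc53cf3f52a6dee9989cc6517ce99",
  "table2_GCA_011032805.1.tsv": "7a621fd1b0c86a6db122f83784b1b5be7f513069e613b4ced0816b32d2c1edc4",
  "table2_GCA_902806645.1.tsv": "71f7678137358964da5e60de58daf3be4706aaad3291abdbbaf41c0e0a83e28a"
}
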
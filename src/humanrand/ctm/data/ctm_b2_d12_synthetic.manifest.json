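{
 "resource": "ctm_b2_d12_synthetic.tsv",
 "source_label": "synthetic CTM table: sample 5-state binary Turing-machine run, lengths 1-9 direct, remainder by window-mean extension",
 "sha256": "3e538443e20ecc65c0ffb9386ea4336844863ba88868a0ea10bf19afd8c13d72",
 "n_canonical_entries": 2142,
 "n_states": 5,
 "method": "sample",
 "direct_lengths": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9
 ],
 "extension": "window-mean at the longest covered length",
 "total_halting": 4219489588,
 "n_samples": 2500000000,
 "sample_seed": 52000
}
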
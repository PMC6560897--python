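{
  "ambiguity_lexicon.tsv": "5d6307b17649ac488e9c5b009a4665d1de789ef9e65c50117052ec0feacc5c37",
  "cim_list.tsv": "b43badb6094438f393692a8730bcff98a4237c8476d699f3072bdd34c06f349f",
  "deg_overlap_by_series.tsv": "0df7a26f7a4ee08fba61f3524820916e90e755208a19cb2eac0f026876aa1e78",
  "discovery_scores.tsv": "c14b27b84d65cd793035f15d31d3afa31eeae8d284b6fee4f4ffd563bf2a615b",
  "tissue_atlas_synthetic.tsv": "41ad3f8889fb3b48bedc48507baf11627723ba1122595a44e48508118691c01a",
  "tissue_groups.tsv": "890d1b0ac5359ea1dc05ca6662fe58797e78ca948883ed7150970f5d77aef2b7"
}
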
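{
  "version": 1,
  "organism": "Thermotoga maritima",
  "protein": "reverse gyrase",
  "comment": "Named residue spans (author numbering) used by the CLI for fit and contact selections. The latch spans are taken from the structural definition of the latch insertion in helicase subdomain H2; the remaining subdomain boundaries are approximate conveniences for whole-domain selections and carry no analytical weight.",
  "selections": {
    "latch": "A:389-459",
    "latch_globular": "A:395-455",
    "minimal_latch": "A:387-400",
    "helicase": "A:1-617",
    "helicase_minus_latch": "A:1-388,A:460-617",
    "helicase_minlatch_construct": "A:1-386,A:401-617",
    "topoisomerase": "A:618-1104",
    "all_minus_latch": "A:1-388,A:460-1104",
    "all_minus_minimal_latch": "A:1-386,A:401-1104"
  }
}
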
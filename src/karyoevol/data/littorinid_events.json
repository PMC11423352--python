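{
 "schema_version": "1",
 "kind": "eventset",
 "branch": [
  "ALG-root",
  "littorinid"
 ],
 "fissions": [
  {
   "alg": "ALG2",
   "products": [
    "ALG2-1",
    "ALG2-2"
   ],
   "support": null,
   "member_genes": null
  },
  {
   "alg": "ALG4",
   "products": [
    "ALG4-1",
    "ALG4-2"
   ],
   "support": null,
   "member_genes": null
  },
  {
   "alg": "ALG13",
   "products": [
    "ALG13-1",
    "ALG13-2"
   ],
   "support": null,
   "member_genes": null
  },
  {
   "alg": "ALG10",
   "products": [
    "ALG10-1",
    "ALG10-2"
   ],
   "support": null,
   "member_genes": null
  }
 ],
 "fusions": [
  {
   "members": [
    "ALG16",
    "ALG2-1",
    "ALG5"
   ],
   "chromosome": "L2",
   "tally": 2
  },
  {
   "members": [
    "ALG11",
    "ALG2-2"
   ],
   "chromosome": "L3",
   "tally": 1
  },
  {
   "members": [
    "ALG12",
    "ALG4-1"
   ],
   "chromosome": "L1",
   "tally": 1
  }
 ]
}
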
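{
 "schema_version": "1",
 "kind": "eventset",
 "branch": [
  "ALG-root",
  "scallop"
 ],
 "fissions": [
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
   "alg": "ALG4",
   "products": [
    "ALG4-1",
    "ALG4-2"
   ],
   "support": null,
   "member_genes": null
  },
  {
   "alg": "ALG2",
   "products": [
    "ALG2-1",
    "ALG2-2"
   ],
   "support": null,
   "member_genes": null
  }
 ],
 "fusions": [
  {
   "members": [
    "ALG16",
    "ALG5"
   ],
   "chromosome": "PY2",
   "tally": 1
  }
 ]
}
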
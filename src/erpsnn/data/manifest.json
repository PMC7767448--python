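{
  "version": 1,
  "files": {
    "grid1471": {
      "file": "grid1471_synthetic.tsv",
      "sha256": "a767c4c4dc945af8ff656d08d34ddaebd79c85f5acccbbd9c147aafaac09590d",
      "rows": 1471
    },
    "montage62": {
      "file": "montage62.tsv",
      "sha256": "28f0250f3e3c8c66e8458c82b735a9d809fad07199f686461a1b7525b772338a",
      "rows": 62
    },
    "regions_fig5": {
      "file": "regions_fig5.tsv",
      "sha256": "903e7724400438c493d8562b2f5cf01ccf115bcfc1b5de212b1a2f1eb65d195f",
      "rows": 62
    }
  }
}
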
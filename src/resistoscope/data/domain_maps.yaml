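# Default domain annotations, inclusive author-numbered residue ranges.
# NbNRC2: the WHD/LRR ranges share boundary residue 497; earlier-label
# precedence assigns it to WHD, so the LRR effectively starts at 498.
NbNRC2:
  alpha1: [[1, 26]]
  CC: [[27, 133]]
  NB: [[156, 303]]
  HD1: [[315, 376]]
  WHD: [[392, 497]]
  LRR: [[497, 882]]
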
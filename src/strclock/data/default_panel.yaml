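# Default 37-value Y-STR panel: union of the Yfiler Plus and PowerPlex Y23
# marker sets plus eight additional single markers (DYS504, DYS525, DYS552,
# DYS505, DYS537, DYS445, Y-GATA-A10, GGAAT1B07).  DYS385 and DYF387S1 are
# two-copy markers, so 35 named loci carry 37 repeat values.  The uniform
# per-locus rate is the published average for this marker count
# (0.0039 mutations / locus / generation); override per locus as needed.
default_mu: 0.0039
loci:
  DYS19: {}
  DYS389I: {}
  DYS389II: {}
  DYS390: {}
  DYS391: {}
  DYS392: {}
  DYS393: {}
  DYS437: {}
  DYS438: {}
  DYS439: {}
  DYS448: {}
  DYS449: {}
  DYS456: {}
  DYS458: {}
  DYS460: {}
  DYS481: {}
  DYS518: {}
  DYS533: {}
  DYS549: {}
  DYS570: {}
  DYS576: {}
  DYS627: {}
  DYS635: {}
  DYS643: {}
  Y-GATA-H4: {}
  DYS504: {}
  DYS525: {}
  DYS552: {}
  DYS505: {}
  DYS537: {}
  DYS445: {}
  Y-GATA-A10: {}
  GGAAT1B07: {}
  DYS385: {multicopy: true}
  DYF387S1: {multicopy: true}
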
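# Detoxification family vocabularies: INTERPRO / PFAM domain identifiers
# per enzyme or transporter family.  NR (nuclear receptors) has no domain
# rule; its membership is supplied as a curated gene list.
CYP:
  - PF00067
  - IPR001128
  - IPR002397
  - IPR002401
  - IPR002402
  - IPR002403
SDR:
  - PF00106
  - IPR002198
UGT:
  - PF00201
  - IPR002213
GST:
  - IPR010987
  - IPR004045
  - IPR004046
  - PF02798
  - IPR005442
  - IPR003082
  - PF00043
ABC:
  - IPR003439
  - IPR011527
  - PF00005
  - IPR010509
  - PF06472
NR: []
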
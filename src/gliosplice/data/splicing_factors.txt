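# Default splicing-factor panel: recognized prognostic splicing factors in
# cancer, particularly glioma.  One HGNC symbol per line; replace freely.
CLK2
ELAVL1
HNRNPA2B1
HNRNPH1
PTBP1
SNRPB
SRSF1
SRSF2
SRSF3
SRSF7
SRSF9
SRSF10
CELF2
MBNL2
QKI
RBFOX2
RBM4
RBM5
RBM6
RBM10
RBM11
SRSF5
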
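# Mini restriction-enzyme table: the six worked-assay enzymes plus decoys
# for search tests.  One record per line: NAME SITE [availability].
# SITE is caret notation (G^AATTC) or trailing-offset notation (GAGTC(4/5)).
# A third field of '-' marks an enzyme with no commercial supplier.
PleI    GAGTC(4/5)
EcoRI   G^AATTC
XmnI    GAANN^NNTTC
RsaI    GT^AC
Cac8I   GCN^NGC
XcmI    CCANNNNN^NNNNTGG
AluI    AG^CT
HinfI   G^ANTC
MseI    T^TAA
EcoRV   GAT^ATC
HindIII A^AGCTT
SpeI    A^CTAGT
TaqI    T^CGA
DdeI    C^TNAG
MlyI    GAGTC(5/5)
SchI    GAGTC(5/5)
CviJI   RG^CY   -
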
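# DDR / chromatin-modification gene panel (symbol <tab> class).
# Classes are best-effort pathway annotations for network node labelling:
# DDR = DNA damage response, CM = chromatin modification, both = overlapping.
ARID1A	CM
ARID2	CM
ASH1L	CM
ASXL2	CM
ATM	DDR
ATR	DDR
BPTF	CM
BRCA2	DDR
CDKN1A	DDR
CDKN2A	DDR
CHD6	CM
CHD7	CM
CREBBP	CM
EP300	CM
ERCC2	DDR
HUWE1	DDR
KANSL1	CM
KDM6A	CM
KMT2A	CM
KMT2C	CM
KMT2D	CM
NCOR1	CM
POLQ	DDR
RB1	both
SETD2	both
SRCAP	CM
STAG2	DDR
TP53	both
TRRAP	both
UBR5	DDR
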
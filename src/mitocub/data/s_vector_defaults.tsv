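# Default wobble selective constraints (s values) for relative adaptiveness.
# One pairing per line: <anticodon base 34>:<codon base 3> TAB s-value.
# Watson-Crick pairings carry s = 0; wobble pairings carry the published
# defaults of the reference tAI implementation. "I" denotes inosine at
# position 34 (a deaminated A34, applied when assume_inosine is set).
A:U	0
C:G	0
G:C	0
U:A	0
I:U	0
G:U	0.41
I:C	0.28
I:A	0.9999
U:G	0.68
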
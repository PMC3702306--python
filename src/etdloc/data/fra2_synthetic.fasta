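>FRA2_SYNTHETIC synthetic carrier, Fra-2 tryptic 20-mer at residues 307-326
GAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLE
GAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLE
KGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVL
EGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVL
EKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAVLEGAVLEKGAV
LEGAVKSSSSGDQSSDSLNSPTLLAL
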
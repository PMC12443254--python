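# Default Ballesteros-Weinstein map for the human 5-HT2A receptor.
# Only positions with literature-anchored residue numbers are shipped;
# add entries (e.g. 6x30, 3x50, 3x46, 6x37, 5x44, 3x36, 6x55) from your
# own numbering before using DOFs that reference them.
receptor: 5-HT2A
entries:
  6x48: 336
  6x44: 332
  6x41: 329
  5x58: 254
  5x46: 242
  5x50: 246
  7x53: 380
  7x49: 376
  7x41: 369
  3x32: 155
  3x40: 163
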
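>synthetic_23S_fragment synthetic stand-in for a 23S rRNA gene 5'-fragment reference
TTAGTAGTCGCGGCGATATAGGTCCTACGGCCGTGACTTGGGCCCAATATTGTGTTTGAACCCAGTCCTC
ACCCAGATGTGATGGCGTGGGTCCTGGTTCCCCCATTCGG
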
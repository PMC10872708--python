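"""Packaged reference sequences used by island typing.

The two tyrosine-recombinase references (xerD, xerC) are SYNTHETIC
stand-ins: deterministic pseudo-random proteins with a bacterial amino-acid
composition, not biological sequences.  They serve as homology anchors —
the synthetic clade generator plants CDSs derived from the same references,
and :mod:`fgikit.island_classify` labels a recombinase hit by its
best-scoring reference.  Swap in curated XerD/XerC sequences here to type
islands in real genomes.

The 20-mer below is the 3'-terminal motif of the tRNA-Lys(ctt) gene whose
direct repeats mark additive-island cassette boundaries.
"""

TRNA_LYS_TERMINAL_20MER = "ACCAGCTGAGCTAATCCCCC"

XERD = (
    "MISNVDHLLGQCWGNVVAFLVGLSQLHFRYRYLVQAVIPKRTPPFNNLVPIRCGMEQVVY"
    "RGLRDPKTFEETARNGIEIPVGSGLRQDNVGNPYLSLEKIFVLYASIRATLETGKELMIK"
    "VWPKAAPIRADRHRKDDMESGELILAVRVGLGRVKEQVLGRFEKKKMPWNVSETAAITAK"
    "LRLAAENEIGIRFTALDEPEEPGGYIIQYRRPVFLEPDLSALQELPLLVNGVDQVTSWKR"
    "DDRHMFHLDAAAQASIQKVYPAIMLRWDLPKAGADNLLGLLSMAAALGKLVVILNSKC"
)

XERC = (
    "MVAQLKNIIPEANSLLLRETANEFRFNLGTGWSVQSAFVKWLMVFKVNAERENLTILAWW"
    "NVDDMYRILQIMLNDDMAAPANQPTMISAKGAYYEDSSVTIVQIGVEMQPIGDLLMPKKA"
    "VQGLDLEILNQSIIWEIWLFAHARTSSYEKSAKFLQEDAAEDFRARMYNIRNNTMQHGKR"
    "ISDGLMISGDEDPLNKALHGLSFTLTTIEQLKSVDDYASQREGELTFRKKRQKLLFQLPH"
    "TLHLGIRKLPGGLNLGHQKIPVLAKLAVEWIVTEFKHAQLTRFVRDKIGANGPDMSPD"
)

RECOMBINASE_REFERENCES: dict[str, str] = {"xerD": XERD, "xerC": XERC}
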
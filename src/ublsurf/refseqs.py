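"""Reference sequences for the FAT10/ubiquitin comparison.

Human FAT10 (ubiquitin D, UniProt O15205, 165 aa) and human ubiquitin
(the 76-aa monomer).  FAT10 landmarks, author numbering: Cys at 7, 9, 134,
160, 162; inter-domain linker KPSDE at 82-86; disordered N-terminal tail
APNASC at 2-7; hydrophobic-patch-equivalent positions E15/L51/K79
(N-domain) and S95/T133/A159 (C-domain), matching ubiquitin's patch
L8/I44/V70.

Domain boundaries follow the expression constructs used for the structural
work: N-domain = residues 5-86, C-domain = residues 85-165.
"""

FAT10_HUMAN = (
    "MAPNASCLCVHVRSEEWDLMTFDANPYDSVKKIKEHVRSKTKVPVQDQVLLLGSKILKPRRSLSSYGIDK"
    "EKTIHLTLKVVKPSDEELPLFLVESGDEAKRLLLQVRRSSSVAQVKAMIETKTGIIPETQIVTCNGKRLE"
    "DGKMMADYGIRKGNLLFLACYCIGG"
)

UBIQUITIN_HUMAN = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLV"
    "LRLRGG"
)

#: inclusive author-numbering boundaries of the two FAT10 UBL domains
FAT10_N_DOMAIN = (5, 86)
FAT10_C_DOMAIN = (85, 165)

#: ubiquitin hydrophobic patch (L8, I44, V70)
UB_PATCH = (8, 44, 70)


def fat10_domain(which: str) -> tuple[str, int]:
    """Return (sequence, first author residue number) of a FAT10 domain."""
    if which == "N":
        lo, hi = FAT10_N_DOMAIN
    elif which == "C":
        lo, hi = FAT10_C_DOMAIN
    else:
        raise ValueError("which must be 'N' or 'C'")
    return FAT10_HUMAN[lo - 1 : hi], lo
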
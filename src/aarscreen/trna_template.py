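"""Canonical tRNA cloverleaf template shared by the simulator and the parser.

A fixed 76-nt consensus (5-nt variable loop) is bundled per isotype; type II
tRNAs replace the variable loop with a longer V-arm. All arms have fixed
length, so a gene's cloverleaf segmentation is fully determined by its length
plus the anchored arm layout; the parser validates the acceptor stem on top.

Canonical numbering (1..76):
  1-7    acceptor stem 5' half          49-53  T-stem 5' half
  8-9    connector                      54-60  T-loop
  10-13  D-stem 5' half                 61-65  T-stem 3' half
  14-21  D-loop                         66-72  acceptor stem 3' half
  22-25  D-stem 3' half                 73     discriminator base
  26     connector                      74-76  3'-CCA
  27-31  anticodon stem 5' half
  32-38  anticodon loop (anticodon = 34-36)
  39-43  anticodon stem 3' half
  44-48  variable region (5 nt type I; the V-arm in type II)
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# 5' half segments (fixed content; stems pair Watson-Crick with their 3' halves)
ACC5 = "GCCGAGG"        # canonical 1-7
LINK89 = "TA"           # 8-9
DSTEM5 = "GCTC"         # 10-13
DLOOP = "AGTTGGTA"      # 14-21
DSTEM3 = revcomp(DSTEM5)   # 22-25
LINK26 = "A"            # 26
ACSTEM5 = "CTGGC"       # 27-31
ACSTEM3 = revcomp(ACSTEM5)  # 39-43
VARLOOP = "ACGGT"       # 44-48 (type I short loop)
TSTEM5 = "CGTGG"        # 49-53
TLOOP = "TTCGAAT"       # 54-60
TSTEM3 = revcomp(TSTEM5)   # 61-65
ACC3 = revcomp(ACC5)    # 66-72
CCA = "CCA"             # 74-76

ANTICODON = {"Tyr": "GTA", "Trp": "CCA"}

# lengths of the invariant flanks around the variable region
PREFIX_LEN = 43   # canonical 1..43
SUFFIX_LEN = 28   # canonical 49..76
CORE_LEN = PREFIX_LEN + SUFFIX_LEN  # 71 nt: a tRNA gene is CORE_LEN + var nt

# canonical positions the simulator never mutates (identity elements)
CONSTRAINED_CANONICAL = {1, 34, 35, 36, 72, 73}

_VARM_FILL = "GCGTACGATCGGCTAAGCTTGCACGTGCAGTTCGAC"


def v_arm_sequence(length: int) -> str:
    """Deterministic V-arm filler of the requested length."""
    reps = (length // len(_VARM_FILL)) + 1
    return (_VARM_FILL * reps)[:length]


def build_trna(isotype: str,
               pair_1_72: tuple[str, str] = ("G", "C"),
               n73: str = "A",
               v_arm_len: int = 0,
               anticodon: str | None = None) -> str:
    """Assemble the template gene for one spec (no mutations applied)."""
    if anticodon is None:
        anticodon = ANTICODON[isotype]
    acc5 = pair_1_72[0] + ACC5[1:]
    acc3 = ACC3[:6] + pair_1_72[1]
    ac_loop = "CT" + anticodon + "AA"
    var = VARLOOP if v_arm_len == 0 else v_arm_sequence(v_arm_len)
    return (acc5 + LINK89 + DSTEM5 + DLOOP + DSTEM3 + LINK26 +
            ACSTEM5 + ac_loop + ACSTEM3 + var +
            TSTEM5 + TLOOP + TSTEM3 + acc3 + n73 + CCA)


def acceptor_pair_indices(var_len: int) -> list[tuple[int, int]]:
    """0-based index pairs (5' half, 3' half) of the 7 acceptor-stem pairs."""
    # canonical k (k=1..7) pairs with canonical 73-k; canonical c>=49 sits at
    # index c - 6 + var_len (0-based)
    return [(k - 1, 67 - k + var_len) for k in range(1, 8)]


def is_paired(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS or (a, b) in WOBBLE_PAIRS
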
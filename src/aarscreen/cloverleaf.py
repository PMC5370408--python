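"""Cloverleaf folding, identity-element extraction and identity typing.

The identity elements that separate bacterial from archaeal/eukaryal
tRNA(Tyr)/tRNA(Trp) live at fixed canonical positions: the 1-72 base pair at
the top of the acceptor stem, the discriminator base N73, the anticodon, and
the presence of a long variable arm. Folding here is an anchored template
alignment: all arms of the bundled consensus have fixed length and indels are
confined to the variable region, so the optimal anchored alignment is the
direct segmentation (variable-region length = gene length - 71), validated by
requiring >= 6 of 7 Watson-Crick or G.U pairs in the acceptor stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import trna_template as T

DOMAIN_BACTERIAL = "bacterial"
DOMAIN_ARCHAEAL = "archaeal_eukaryal"
DOMAIN_CHIMERIC = "chimeric_C1G72_with_Varm"
DOMAIN_AMBIGUOUS = "ambiguous"

#: a variable region of at least this many nt counts as a V-arm (type II)
V_ARM_MIN_LEN = 10

_SEGMENT_LAYOUT = [
    # (name, length) for the invariant 5' flank, then var, then the 3' flank
    ("acceptor_5p", 7), ("connector_8_9", 2), ("d_stem_5p", 4),
    ("d_loop", 8), ("d_stem_3p", 4), ("connector_26", 1),
    ("anticodon_stem_5p", 5), ("anticodon_loop", 7), ("anticodon_stem_3p", 5),
]
_SUFFIX_LAYOUT = [
    ("t_stem_5p", 5), ("t_loop", 7), ("t_stem_3p", 5),
    ("acceptor_3p", 7), ("discriminator", 1), ("cca", 3),
]


@dataclass
class Cloverleaf:
    """A tRNA gene mapped onto canonical cloverleaf segments."""

    sequence: str
    foldable: bool
    reason: Optional[str] = None
    segments: dict = field(default_factory=dict)   # name -> (start, end) 0-based half-open
    canonical: dict = field(default_factory=dict)  # canonical number -> 0-based index
    v_arm_span: Optional[tuple[int, int]] = None
    v_arm_len: int = 0
    acceptor_pairs_ok: int = 0

    @property
    def discriminator_index(self) -> Optional[int]:
        return self.canonical.get(73)

    @property
    def anticodon_indices(self) -> Optional[tuple[int, int, int]]:
        if 34 not in self.canonical:
            return None
        return (self.canonical[34], self.canonical[35], self.canonical[36])


@dataclass
class IdentityProfile:
    pair_1_72: tuple[str, str]
    n73: str
    v_arm_present: bool
    v_arm_len: int
    anticodon: str
    isotype_hint: str  # Tyr / Trp / other


@dataclass
class IdentityCall:
    isotype: str
    domain_type: str
    evidence: list  # (element, observed, expected_per_type)


def fold_cloverleaf(seq: str) -> Cloverleaf:
    """Fold a coding-strand tRNA gene into the canonical cloverleaf.

    Returns a structured "unfoldable" result (never raises) when no
    admissible fold exists; raises ``ValueError`` only on precondition
    violations (length outside 60..110 or bad alphabet).
    """
    seq = seq.upper()
    if not 60 <= len(seq) <= 110:
        raise ValueError(f"sequence length {len(seq)} outside 60..110")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"bad alphabet characters: {sorted(set(seq) - set('ACGTN'))}")

    var_len = len(seq) - T.CORE_LEN
    if var_len < 0:
        return Cloverleaf(seq, False, reason="shorter than the invariant arms")

    pairs_ok = sum(
        T.is_paired(seq[i], seq[j]) for i, j in T.acceptor_pair_indices(var_len)
    )
    if pairs_ok < 6:
        return Cloverleaf(seq, False,
                          reason=f"acceptor stem pairing {pairs_ok}/7 below 6",
                          acceptor_pairs_ok=pairs_ok)

    segments: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, length in _SEGMENT_LAYOUT:
        segments[name] = (pos, pos + length)
        pos += length
    segments["variable"] = (pos, pos + var_len)
    pos += var_len
    for name, length in _SUFFIX_LAYOUT:
        segments[name] = (pos, pos + length)
        pos += length

    canonical: dict[int, int] = {}
    for c in range(1, 44):
        canonical[c] = c - 1
    for c in range(49, 77):
        canonical[c] = c - 6 + var_len
    # variable-region positions are flagged via the span, not numbered

    return Cloverleaf(
        seq, True, segments=segments, canonical=canonical,
        v_arm_span=segments["variable"], v_arm_len=var_len,
        acceptor_pairs_ok=pairs_ok,
    )


def extract_identity_profile(cl: Cloverleaf) -> IdentityProfile:
    """Read the identity elements off a folded cloverleaf."""
    if not cl.foldable:
        raise ValueError("cannot extract identity elements from an unfoldable result")
    s = cl.sequence
    pair = (s[cl.canonical[1]], s[cl.canonical[72]])
    n73 = s[cl.canonical[73]]
    a, b, c = cl.anticodon_indices
    anticodon = s[a] + s[b] + s[c]
    hint = {"GTA": "Tyr", "CCA": "Trp"}.get(anticodon, "other")
    return IdentityProfile(
        pair_1_72=pair, n73=n73,
        v_arm_present=cl.v_arm_len >= V_ARM_MIN_LEN,
        v_arm_len=cl.v_arm_len, anticodon=anticodon, isotype_hint=hint,
    )


def identity_rule(isotype: str, pair_1_72: tuple[str, str], n73: str,
                  v_arm_present: bool) -> str:
    """The identity-domain rule table for Tyr and Trp.

    Tyr: G1-C72 with a V-arm is bacterial; C1-G72 without a V-arm is
    archaeal/eukaryal; C1-G72 *with* a V-arm is the chimeric combination seen
    in CPR bacteria; anything else is ambiguous.
    Trp: G73 is bacterial; A73 with G1-C72 is archaeal/eukaryal; else ambiguous.
    """
    if isotype == "Tyr":
        if pair_1_72 == ("G", "C") and v_arm_present:
            return DOMAIN_BACTERIAL
        if pair_1_72 == ("C", "G") and not v_arm_present:
            return DOMAIN_ARCHAEAL
        if pair_1_72 == ("C", "G") and v_arm_present:
            return DOMAIN_CHIMERIC
        return DOMAIN_AMBIGUOUS
    if isotype == "Trp":
        if n73 == "G":
            return DOMAIN_BACTERIAL
        if n73 == "A" and pair_1_72 == ("G", "C"):
            return DOMAIN_ARCHAEAL
        return DOMAIN_AMBIGUOUS
    raise ValueError(f"isotype {isotype!r} not classifiable (expected Tyr or Trp)")


def classify_identity(profile: IdentityProfile) -> IdentityCall:
    """Type a tRNA's identity domain from its extracted elements."""
    isotype = profile.isotype_hint
    if isotype not in ("Tyr", "Trp"):
        raise ValueError(
            f"anticodon {profile.anticodon!r} gives isotype hint {isotype!r}: "
            "not classifiable")
    domain = identity_rule(isotype, profile.pair_1_72, profile.n73,
                           profile.v_arm_present)
    pair_txt = f"{profile.pair_1_72[0]}1-{profile.pair_1_72[1]}72"
    evidence = []
    if isotype == "Tyr":
        evidence.append(("pair_1_72", pair_txt,
                         {"bacterial": "G1-C72", "archaeal_eukaryal": "C1-G72"}))
        evidence.append(("v_arm", f"{profile.v_arm_len} nt",
                         {"bacterial": "present (>=10 nt)",
                          "archaeal_eukaryal": "absent"}))
    else:
        evidence.append(("n73", profile.n73,
                         {"bacterial": "G", "archaeal_eukaryal": "A"}))
        evidence.append(("pair_1_72", pair_txt,
                         {"archaeal_eukaryal": "G1-C72"}))
    if domain == DOMAIN_AMBIGUOUS:
        evidence.append(("conflict",
                         f"pair={pair_txt}, n73={profile.n73}, "
                         f"v_arm={'present' if profile.v_arm_present else 'absent'}",
                         {"note": "element combination matches no single domain"}))
    return IdentityCall(isotype=isotype, domain_type=domain, evidence=evidence)
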
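"""Synthetic contigs, tRNA genes and protein families with known ground truth.

Everything the screening pipeline detects can be planted here with explicit,
seeded control: tRNA identity elements (1-72 pair, discriminator N73, V-arm,
anticodon), class I aaRS motifs and domain fusions, the locus layouts of the
TrpRS-A operons, and protein families evolved along a known tree (optionally
one tree shared by two families, for the congruence test). Determinism is a
contract: identical spec + seed gives identical bytes out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import cloverleaf as C
from . import locus as L
from . import trna_template as T
from .aars import AA20, Reference, ArchitectureRefs
from .tree import Node, Tree, random_topology

_AA = np.array(list(AA20))
_NT = np.array(list("ACGT"))


# ====================================================================== specs

@dataclass(frozen=True)
class TrnaSpec:
    isotype: str
    pair_1_72: tuple[str, str] = ("G", "C")
    n73: str = "A"
    v_arm_len: int = 0
    anticodon: Optional[str] = None   # default: GTA for Tyr, CCA for Trp
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.isotype not in ("Tyr", "Trp"):
            raise ValueError(f"isotype: {self.isotype!r} not in {{Tyr, Trp}}")
        for fieldname, base in (("pair_1_72[0]", self.pair_1_72[0]),
                                ("pair_1_72[1]", self.pair_1_72[1]),
                                ("n73", self.n73)):
            if base not in "ACGT":
                raise ValueError(f"{fieldname}: {base!r} is not a base")
        if not (self.v_arm_len == 0 or self.v_arm_len >= 10):
            raise ValueError(f"v_arm_len: {self.v_arm_len} must be 0 or >= 10")
        if self.anticodon is not None and (
                len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT")):
            raise ValueError(f"anticodon: {self.anticodon!r} is not 3 nt")
        if not 0 <= self.mutation_rate <= 0.3:
            raise ValueError(f"mutation_rate: {self.mutation_rate} outside [0, 0.3]")

    @property
    def effective_anticodon(self) -> str:
        return self.anticodon or T.ANTICODON[self.isotype]


@dataclass(frozen=True)
class ProteinFamilySpec:
    family_id: str
    n_leaves: int
    root_length: int = 300
    tree_shape: str = "random_yule"           # or fixed_newick
    newick: Optional[str] = None
    subs_per_site: float = 0.1                # expected root-to-leaf divergence
    planted_motifs: tuple = ()                # ((motif_name, 1-based pos), ...)
    shared_tree_with: Optional[str] = None
    exclude_residues: str = ""                # e.g. "W" for Trp-free families
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 3:
            raise ValueError(f"n_leaves: {self.n_leaves} must be >= 3")
        if self.tree_shape not in ("random_yule", "fixed_newick"):
            raise ValueError(f"tree_shape: {self.tree_shape!r}")
        if self.tree_shape == "fixed_newick" and not self.newick:
            raise ValueError("newick: required for tree_shape=fixed_newick")
        if self.subs_per_site < 0:
            raise ValueError(f"subs_per_site: {self.subs_per_site} < 0")
        spans = sorted(_motif_span(n, p) for n, p in self.planted_motifs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("planted_motifs: positions overlap")
        for _, (s, e) in zip(self.planted_motifs, spans):
            if s < 1 or e > self.root_length:
                raise ValueError(
                    f"planted_motifs: span {s}-{e} outside root_length "
                    f"{self.root_length}")


FEATURE_TEMPLATES = (
    "trna_trp_A73", "orf1", "trprs_a1", "trprs_a2", "trprs_a_like",
    "trprs_bacterial", "trp_repressor", "trna_tyr", "tyrs_archaeal",
    "b2_tyrs", "filler", "orf1_no_motifs",
)


@dataclass(frozen=True)
class ContigSpec:
    layout: tuple
    intergenic_gap: int = 30
    strand: str = "+"
    seed: int = 0
    genome: Optional[str] = None

    def __post_init__(self):
        if not self.layout:
            raise ValueError("layout: must be non-empty")
        for name in self.layout:
            if name not in FEATURE_TEMPLATES:
                raise ValueError(f"layout: unknown feature template {name!r}")
        if self.intergenic_gap < 0:
            raise ValueError(f"intergenic_gap: {self.intergenic_gap} < 0")
        if self.strand not in "+-":
            raise ValueError(f"strand: {self.strand!r} not in {{+, -}}")


# ====================================================================== truth

class TruthTable:
    """Flat per-feature/per-operon/per-family truth records.

    Cell values are JSON-encoded in the TSV serialisation so the table
    round-trips losslessly (lists, tuples and numbers survive).
    """

    def __init__(self, records: Optional[list[dict]] = None):
        self.records = records or []

    def add(self, **record) -> dict:
        self.records.append(record)
        return record

    def of_type(self, record_type: str) -> list[dict]:
        return [r for r in self.records if r.get("record_type") == record_type]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_tsv(self, path) -> None:
        cols = sorted({k for r in self.records for k in r})
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                fh.write("\t".join(
                    json.dumps(r[k], sort_keys=True) if k in r else ""
                    for k in cols) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        with open(path) as fh:
            lines = fh.read().splitlines()
        cols = lines[0].split("\t")
        records = []
        for line in lines[1:]:
            cells = line.split("\t")
            records.append({c: json.loads(v)
                            for c, v in zip(cols, cells) if v != ""})
        return cls(records)

    def __eq__(self, other):
        return isinstance(other, TruthTable) and self.records == other.records

    def __len__(self):
        return len(self.records)


# ====================================================================== tRNA

def generate_trna(spec: TrnaSpec) -> tuple[str, dict]:
    """A tRNA gene with the spec's identity elements planted.

    Identity-element positions (1, 72, 73, anticodon) are never mutated.
    Acceptor-stem pairs 2-7 mutate jointly (a 5'-half substitution rewrites
    the 3'-half complement) so the stem stays base-paired and the gene stays
    foldable at any admissible mutation rate.
    """
    seq = list(T.build_trna(spec.isotype, spec.pair_1_72, spec.n73,
                            spec.v_arm_len, spec.effective_anticodon))
    rng = np.random.default_rng(spec.seed)
    var = spec.v_arm_len or len(T.VARLOOP)   # actual variable-region length
    protected = {0, 33, 34, 35, 66 + var, 67 + var}   # canonical 1,34-36,72,73
    stem_pairs = {i: j for i, j in T.acceptor_pair_indices(var)}
    stem_3p = set(stem_pairs.values())
    for i in range(len(seq)):
        if i in protected or i in stem_3p:
            continue
        if rng.random() >= spec.mutation_rate:
            continue
        base = str(rng.choice(_NT))
        seq[i] = base
        if i in stem_pairs:   # compensatory partner substitution
            seq[stem_pairs[i]] = T.COMPLEMENT[base]
    sequence = "".join(seq)
    record = {
        "record_type": "trna",
        "isotype": spec.isotype,
        "pair_1_72": "".join(spec.pair_1_72),
        "n73": spec.n73,
        "v_arm_len": spec.v_arm_len,
        "anticodon": spec.effective_anticodon,
        "domain_type": C.identity_rule(spec.isotype, spec.pair_1_72, spec.n73,
                                       spec.v_arm_len >= C.V_ARM_MIN_LEN),
        "mutation_rate": spec.mutation_rate,
        "seed": spec.seed,
        "length": len(sequence),
    }
    return sequence, record


# ====================================================================== proteins

def _motif_text(name: str, rng) -> tuple[str, list[int]]:
    """Motif instance text and the 0-based offsets of its constrained columns."""
    if name == "HIGH":
        return "HIGH", [0, 1, 2, 3]
    if name == "KMSKS":
        return "KMSKS", [0, 1, 2, 3, 4]
    if name == "FeS_C4":
        spacers = [22, 6, 2]
        text, constrained, off = "", [], 0
        for sp in spacers:
            text += "C" + "".join(rng.choice(_AA, sp))
            constrained.append(off)
            off += 1 + sp
        text += "C"
        constrained.append(off)
        return text, constrained
    raise ValueError(f"unknown motif {name!r}")


def _motif_span(name: str, pos: int) -> tuple[int, int]:
    length = {"HIGH": 4, "KMSKS": 5, "FeS_C4": 34}[name]
    return pos, pos + length - 1


def _random_protein(length: int, rng, exclude: str = "") -> str:
    alphabet = np.array([a for a in AA20 if a not in exclude])
    return "".join(rng.choice(alphabet, length))


@dataclass
class FamilyResult:
    family_id: str
    records: list            # (leaf id, protein sequence)
    tree: Tree
    root_sequence: str
    constrained: set         # 0-based protected columns
    truth: list              # truth records


def _yule_tree(n_leaves: int, rng) -> Tree:
    labels = [f"t{i + 1:02d}" for i in range(n_leaves)]
    return random_topology(labels, rng)


def _scale_branch_lengths(tree: Tree, subs_per_site: float, rng) -> None:
    """Draw Exp(1) branch lengths, then scale so the mean root-to-leaf path
    equals ``subs_per_site`` (the spec's divergence scale)."""
    branches = [n for n in tree.preorder() if n.parent is not None]
    for b in branches:
        b.length = float(rng.exponential(1.0))
    depths = []
    for leaf in tree.leaves():
        d, node = 0.0, leaf
        while node.parent is not None:
            d += node.length
            node = node.parent
        depths.append(d)
    mean_depth = float(np.mean(depths)) or 1.0
    scale = subs_per_site / mean_depth if subs_per_site > 0 else 0.0
    for b in branches:
        b.length *= scale


def generate_protein_family(spec: ProteinFamilySpec,
                            topology: Optional[Tree] = None) -> FamilyResult:
    """Evolve a protein family along a known tree.

    Poisson substitutions with a flat 20-letter replacement distribution;
    planted-motif columns are never touched. ``topology`` (when given, e.g.
    for a shared-tree pair) overrides the spec's tree shape.
    """
    rng = np.random.default_rng(spec.seed)
    if topology is not None:
        tree = topology.copy()
        if len(tree.leaf_labels()) != spec.n_leaves:
            raise ValueError(
                f"shared topology has {len(tree.leaf_labels())} leaves, "
                f"spec.n_leaves is {spec.n_leaves}")
    elif spec.tree_shape == "fixed_newick":
        tree = Tree.from_newick(spec.newick)
        if len(tree.leaf_labels()) != spec.n_leaves:
            raise ValueError(
                f"fixed_newick has {len(tree.leaf_labels())} leaves, "
                f"spec.n_leaves is {spec.n_leaves}")
    else:
        tree = _yule_tree(spec.n_leaves, rng)
    if topology is not None or spec.tree_shape == "random_yule":
        _scale_branch_lengths(tree, spec.subs_per_site, rng)

    root = list(_random_protein(spec.root_length, rng, spec.exclude_residues))
    constrained: set[int] = set()
    for name, pos in spec.planted_motifs:
        text, offsets = _motif_text(name, rng)
        root[pos - 1:pos - 1 + len(text)] = list(text)
        constrained.update(pos - 1 + o for o in offsets)
    free = np.array([i for i in range(spec.root_length) if i not in constrained])
    alphabet = np.array([a for a in AA20 if a not in spec.exclude_residues])

    seqs: dict[int, list[str]] = {id(tree.root): root}
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_seq = seqs[id(node.parent)]
        child = list(parent_seq)
        n_sub = rng.poisson(node.length * len(free)) if len(free) else 0
        if n_sub:
            sites = rng.choice(free, size=n_sub)
            repl = rng.choice(alphabet, size=n_sub)
            for s, r in zip(sites, repl):
                child[int(s)] = str(r)
        seqs[id(node)] = child

    records = sorted(
        ((leaf.label, "".join(seqs[id(leaf)])) for leaf in tree.leaves()),
        key=lambda t: t[0])
    truth = [{
        "record_type": "family",
        "family_id": spec.family_id,
        "n_leaves": spec.n_leaves,
        "newick": tree.to_newick(support_as_label=False),
        "planted_motifs": [list(m) for m in spec.planted_motifs],
        "subs_per_site": spec.subs_per_site,
        "shared_tree_with": spec.shared_tree_with,
        "seed": spec.seed,
    }]
    return FamilyResult(spec.family_id, records, tree, "".join(root),
                        constrained, truth)


def generate_coevolved_pair(spec_a: ProteinFamilySpec,
                            spec_b: ProteinFamilySpec) -> tuple[FamilyResult, FamilyResult]:
    """Two families on one true topology (the co-evolution scenario)."""
    fam_a = generate_protein_family(spec_a)
    spec_b = replace(spec_b, shared_tree_with=spec_a.family_id)
    fam_b = generate_protein_family(spec_b, topology=fam_a.tree)
    return fam_a, fam_b


# ====================================================================== ancestors

_ANCESTOR_SEED = 20170221

_ANCESTOR_PLAN = {
    # name: (length, motifs, exclude_residues)
    "trprs_bacterial": (320, (("HIGH", 40), ("KMSKS", 240)), "W"),
    "tyrs_archaeal": (300, (("HIGH", 45), ("KMSKS", 220)), ""),
    "trprs_a1": (300, (("HIGH", 42), ("KMSKS", 225)), "W"),
    "trprs_a2": (300, (("HIGH", 42), ("KMSKS", 210), ("FeS_C4", 260)), ""),
    "trprs_a_like": (320, (("HIGH", 50), ("KMSKS", 230)), ""),
    "orf1": (180, (("HIGH", 30), ("KMSKS", 120)), "W"),
    "b2_domain": (90, (), ""),
    "linker": (25, (), ""),
    "s4_domain": (80, (), ""),
    "trp_repressor": (100, (), ""),
    "filler": (150, (), ""),
}


def lineage_ancestors() -> dict[str, str]:
    """Deterministic synthetic ancestor proteins, one per lineage/domain.

    These are the package's own constructs (independent random sequences
    with the diagnostic motifs planted); they stand in for curated family
    representatives and double as the labelled reference set in tests.
    """
    out = {}
    for i, (name, (length, motifs, excl)) in enumerate(sorted(_ANCESTOR_PLAN.items())):
        rng = np.random.default_rng(_ANCESTOR_SEED + i)
        seq = list(_random_protein(length, rng, excl))
        for mname, pos in motifs:
            text, _ = _motif_text(mname, rng)
            seq[pos - 1:pos - 1 + len(text)] = list(text)
        out[name] = "".join(seq)
    out["b2_tyrs"] = out["b2_domain"] + out["linker"] + out["tyrs_archaeal"]
    return out


def default_reference_set() -> list[Reference]:
    """Labelled aaRS references backing nearest-reference lineage typing."""
    anc = lineage_ancestors()
    return [
        Reference("ref_trprs_a1", "TrpRS", "TrpRS_A1", anc["trprs_a1"]),
        Reference("ref_trprs_a2", "TrpRS", "TrpRS_A2", anc["trprs_a2"]),
        Reference("ref_trprs_a_like", "TrpRS", "TrpRS_A_like", anc["trprs_a_like"]),
        Reference("ref_trprs_bacterial", "TrpRS", "bacteria_type", anc["trprs_bacterial"]),
        Reference("ref_tyrs_archaeal", "TyrRS", "archaea_eukarya_type", anc["tyrs_archaeal"]),
    ]


def default_architecture_refs() -> ArchitectureRefs:
    anc = lineage_ancestors()
    return ArchitectureRefs(b2=anc["b2_domain"], s4=anc["s4_domain"])


# ====================================================================== contigs

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(protein: str) -> str:
    return "ATG" + "".join(_CODON[a] for a in protein) + "TAA"


_TEMPLATE_ROLE = {
    "trna_trp_A73": L.TRNA_TRP_A,
    "orf1": L.ORF1,
    "trprs_a1": L.TRPRS_A1,
    "trprs_a2": L.TRPRS_A2,
    "trprs_a_like": L.TRPRS_ALIKE,
    "trprs_bacterial": L.TRPRS_BACT,
    "trp_repressor": L.TRPR,
    "trna_tyr": L.TRNA_TYR,
    "tyrs_archaeal": L.OTHER,
    "b2_tyrs": L.OTHER,
    "filler": L.OTHER,
    "orf1_no_motifs": L.OTHER,
}

_TRNA_TEMPLATES = {
    # archaeal-identity tRNA-Trp: A73 with G1-C72
    "trna_trp_A73": dict(isotype="Trp", pair_1_72=("G", "C"), n73="A", v_arm_len=0),
    # archaeal-identity tRNA-Tyr: C1-G72, no V-arm
    "trna_tyr": dict(isotype="Tyr", pair_1_72=("C", "G"), n73="A", v_arm_len=0),
}


def _feature_sequence(name: str, anc: dict[str, str], rng) -> tuple[str, str, dict]:
    """(kind, nucleotide sequence, extra truth fields) for one template."""
    if name in _TRNA_TEMPLATES:
        spec = TrnaSpec(seed=int(rng.integers(2 ** 31)), **_TRNA_TEMPLATES[name])
        seq, rec = generate_trna(spec)
        return "tRNA", seq, rec
    if name == "orf1_no_motifs":
        prot = anc["orf1"]
        prot = prot[:29] + "AAAA" + prot[33:119] + "AAAAA" + prot[124:]
        return "CDS", reverse_translate(prot), {"protein_length": len(prot)}
    key = {"trp_repressor": "trp_repressor", "filler": "filler"}.get(name, name)
    prot = anc[key]
    return "CDS", reverse_translate(prot), {"protein_length": len(prot)}


def generate_contigs(specs: Sequence[ContigSpec]) -> tuple[dict, list, TruthTable]:
    """Contigs + GFF3 rows + truth for a list of layout specs.

    GFF3 coordinates are 1-based inclusive; minus-strand layouts keep the
    layout order as transcription order (features appear reverse-ordered in
    genomic coordinates and reverse-complemented in sequence space).
    """
    anc = lineage_ancestors()
    contigs: dict[str, str] = {}
    rows: list[dict] = []
    truth = TruthTable()
    for ci, spec in enumerate(specs):
        contig_id = f"contig_{ci + 1:03d}"
        genome = spec.genome or contig_id
        rng = np.random.default_rng(spec.seed)
        parts, feats = [], []
        pos = 1
        lead = int(rng.integers(20, 60))
        parts.append("".join(rng.choice(_NT, lead)))
        pos += lead
        for fi, name in enumerate(spec.layout):
            kind, seq, extra = _feature_sequence(name, anc, rng)
            feats.append({"template": name, "kind": kind, "start": pos,
                          "end": pos + len(seq) - 1, "extra": extra})
            parts.append(seq)
            pos += len(seq)
            gap_seq = "".join(rng.choice(_NT, spec.intergenic_gap))
            parts.append(gap_seq)
            pos += spec.intergenic_gap
        tail = int(rng.integers(20, 60))
        parts.append("".join(rng.choice(_NT, tail)))
        contig_seq = "".join(parts)

        if spec.strand == "-":
            length = len(contig_seq)
            contig_seq = T.revcomp(contig_seq)
            for f in feats:
                f["start"], f["end"] = (length - f["end"] + 1,
                                        length - f["start"] + 1)
        contigs[contig_id] = contig_seq

        for fi, f in enumerate(feats):
            fid = f"{contig_id}_f{fi + 1:02d}"
            rows.append({
                "seqid": contig_id, "source": "aarscreen_sim",
                "type": f["kind"], "start": f["start"], "end": f["end"],
                "score": ".", "strand": spec.strand,
                "phase": "0" if f["kind"] == "CDS" else ".",
                "attributes": {"ID": fid, "Name": f["template"],
                               "genome": genome},
            })
            truth.add(record_type="feature", id=fid, contig=contig_id,
                      genome=genome, template=f["template"], kind=f["kind"],
                      start=f["start"], end=f["end"], strand=spec.strand,
                      role=_TEMPLATE_ROLE[f["template"]], **{
                          k: v for k, v in f["extra"].items()
                          if k not in ("record_type", "seed")})

        # true operon calls: same locus grammar, applied to the true roles
        troles = [_TEMPLATE_ROLE[f["template"]] for f in feats]
        tstarts, tends = [], []
        for f in feats:
            if spec.strand == "-":
                tstarts.append(-f["end"])
                tends.append(-f["start"])
            else:
                tstarts.append(f["start"])
                tends.append(f["end"])
        order = np.argsort(tstarts)
        troles = [troles[i] for i in order]
        ids = [f"{contig_id}_f{i + 1:02d}" for i in order]
        tstarts = [tstarts[i] for i in order]
        tends = [tends[i] for i in order]
        for pattern, idxs, gap in L.match_patterns(troles, tstarts, tends):
            truth.add(record_type="operon", contig=contig_id, genome=genome,
                      pattern=pattern,
                      member_ids=[ids[i] for i in idxs],
                      max_internal_gap=gap)
    rows.sort(key=lambda r: (r["seqid"], r["start"], r["attributes"]["ID"]))
    return contigs, rows, truth
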
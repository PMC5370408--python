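"""End-to-end screening: cloverleaf -> aaRS typing -> locus analysis.

`run_screen` composes the stages over a FASTA + GFF3 input, records
per-record failures as warnings (never aborting the batch), and emits a
report whose tables all trace back to input record ids, with a provenance
block (config hash, version, seeds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import aars as A
from . import cloverleaf as C
from . import fileio as io
from . import locus as L


@dataclass
class PipelineConfig:
    fasta: str
    gff3: str
    reference_fasta: Optional[str] = None
    reference_labels: Optional[str] = None
    similarity_threshold: float = 0.40
    require_fes_for_a2: bool = False
    max_gap: int = 150
    cluster_gap: int = 1000
    bootstrap_replicates: int = 100
    seed: int = 0
    run_phylo: bool = False
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("fasta", "gff3", "reference_fasta", "reference_labels"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def hash(self) -> str:
        # outdir excluded: where a report is written does not change it
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScreenReport:
    trna_table: list = field(default_factory=list)
    protein_table: list = field(default_factory=list)
    operon_table: list = field(default_factory=list)
    genome_table: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    features: list = field(default_factory=list)
    trees: dict = field(default_factory=dict)      # name -> newick

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_tsv(outdir / "trna_report.tsv", self.trna_table)
        io.write_tsv(outdir / "protein_report.tsv", self.protein_table)
        io.write_tsv(outdir / "operon_report.tsv", self.operon_table)
        io.write_tsv(outdir / "genome_summary.tsv", self.genome_table)
        io.write_json(outdir / "report.json", {
            "provenance": self.provenance,
            "warnings": self.warnings,
            "trna": self.trna_table,
            "proteins": self.protein_table,
            "operons": self.operon_table,
            "genomes": self.genome_table,
            "trees": self.trees,
        })


def run_screen(config: PipelineConfig) -> ScreenReport:
    config.validate()
    report = ScreenReport()
    report.provenance = {
        "tool": "aarscreen", "version": __version__,
        "config_hash": config.hash(), "seed": config.seed,
        "similarity_threshold": config.similarity_threshold,
        "max_gap": config.max_gap, "cluster_gap": config.cluster_gap,
    }
    contigs = dict(io.read_fasta(config.fasta))
    rows = io.read_gff3(config.gff3)
    features = L.load_features(rows, contigs)

    refs = []
    if config.reference_fasta and config.reference_labels:
        refs = io.read_reference_set(config.reference_fasta,
                                     config.reference_labels)
    elif config.reference_fasta or config.reference_labels:
        report.warnings.append(
            "reference set incomplete (need FASTA and labels): typing skipped")

    cls_cfg = A.ClassifierConfig(
        similarity_threshold=config.similarity_threshold,
        require_fes_for_a2=config.require_fes_for_a2)
    locus_cfg = L.LocusConfig(max_gap=config.max_gap,
                              cluster_gap=config.cluster_gap)
    L.annotate_features(features, refs, cls_cfg, locus_cfg)
    report.features = features

    for f in features:
        for w in f.warnings:
            report.warnings.append(f"{f.id}: {w}")
        if f.kind == "tRNA":
            row = {"id": f.id, "contig": f.contig, "genome": f.genome,
                   "start": f.start, "end": f.end, "strand": f.strand}
            if isinstance(f.call, C.IdentityCall):
                cl = C.fold_cloverleaf(f.sequence)
                prof = C.extract_identity_profile(cl)
                row.update({
                    "isotype": f.call.isotype,
                    "domain_type": f.call.domain_type,
                    "pair_1_72": "".join(prof.pair_1_72),
                    "n73": prof.n73, "anticodon": prof.anticodon,
                    "v_arm_len": prof.v_arm_len,
                    "evidence": "; ".join(
                        f"{e[0]}={e[1]}" for e in f.call.evidence),
                })
            else:
                row["domain_type"] = "unfoldable_or_unclassifiable"
            report.trna_table.append(row)
        elif f.kind == "CDS":
            row = {"id": f.id, "contig": f.contig, "genome": f.genome,
                   "start": f.start, "end": f.end, "strand": f.strand,
                   "length_aa": len(f.protein or ""), "role": f.role}
            if isinstance(f.call, A.AarsTypeCall):
                row.update({"family": f.call.family,
                            "lineage": f.call.lineage,
                            "best_reference": f.call.best_reference or "",
                            "similarity": round(f.call.similarity, 4)})
            motifs = "; ".join(f"{h.motif_name}@{h.start}-{h.end}"
                               for h in f.motif_hits)
            count, trp_free = (A.audit_trp_content(f.protein)
                               if f.protein else (0, True))
            row.update({"motifs": motifs, "n_trp": count,
                        "trp_free": trp_free})
            report.protein_table.append(row)

    for op in L.detect_operons(features, locus_cfg):
        report.operon_table.append({
            "contig": op.contig, "strand": op.strand, "pattern": op.pattern,
            "members": ",".join(op.member_ids),
            "max_internal_gap": op.max_internal_gap})

    for genome, summ in L.summarize_genome(features).items():
        report.genome_table.append({
            "genome": genome,
            "trna_counts": json.dumps(
                {f"{k[0]}:{k[1]}": v for k, v in sorted(summ.trna_counts.items())}),
            "aars_counts": json.dumps(dict(sorted(summ.aars_counts.items()))),
            "dual_identity": summ.dual_identity})

    if config.run_phylo and refs:
        _phylo_stage(report, config)

    if config.outdir:
        report.write(config.outdir)
    return report


def _phylo_stage(report: ScreenReport, config: PipelineConfig) -> None:
    from . import phylo as P

    fams: dict[str, list] = {}
    for f in report.features:
        if f.kind == "CDS" and isinstance(f.call, A.AarsTypeCall):
            group = "ORF1" if f.role == L.ORF1 else (
                f.call.family if f.call.lineage != "unassigned" else None)
            if group:
                fams.setdefault(group, []).append((f.id, f.protein))
    for group, seqs in sorted(fams.items()):
        if len(seqs) < 4:
            continue
        try:
            msa = P.align_progressive(seqs)
            result = P.bootstrap_support(
                msa, n_replicates=config.bootstrap_replicates,
                seed=config.seed)
            report.trees[group] = result.tree.to_newick()
        except ValueError as exc:
            report.warnings.append(f"phylo[{group}]: {exc}")
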
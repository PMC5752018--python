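"""Readers and writers for the pipeline's file formats, and the top-level run.

Formats
-------
- genetic map: tab-delimited with header ``marker, chromosome, position_cM``
- segments: tab-delimited with header
  ``line_id, donor, chromosome, segment_notation`` (hyphen notation;
  em-dash or ``--`` as the outside separator)
- phenotypes: CSV with header ``line_id, year, plant_id, days_to_heading``
- alleles: FASTA; record ids of the form ``gene|line`` (a bare id is used as
  both gene and line label)
- reports: JSON is the canonical machine output; a TSV mirror of the effects
  table and a VCF-like TSV (CHROM = gene, POS, REF, ALT) for variants are
  written alongside.

Rounding to report precision happens only at serialization; all computation
keeps full precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .allele_diff import (
    AlignParams,
    AlleleSequence,
    ProteinConsequence,
    VariantReport,
    compare_alleles,
    protein_consequence,
)
from .genetic_map import (
    GeneticMap,
    Marker,
    SubstitutedSegment,
    estimate_segment_length,
    format_segment_notation,
    parse_segment_notation,
)
from .phenotype_stats import (
    PhenotypeTable,
    call_qtl_presence,
    dunnett_test,
    summarize_lines,
)
from .qtl_mapping import (
    QTLEffect,
    QTLInterval,
    additive_contribution,
    additive_effect,
    map_qtl,
    round_report,
)

__all__ = [
    "read_genetic_map",
    "write_genetic_map",
    "read_segments",
    "write_segments",
    "read_phenotypes",
    "write_phenotypes",
    "read_fasta",
    "write_fasta",
    "RunConfig",
    "AnalysisReport",
    "run_pipeline",
    "variants_to_vcf_like",
]

logger = logging.getLogger(__name__)


def _check_header(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty genetic map")
    _check_header(df, ["marker", "chromosome", "position_cM"], path)
    markers = []
    for i, row in df.iterrows():
        try:
            markers.append(
                Marker(str(row["marker"]), int(row["chromosome"]), float(row["position_cM"]))
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return GeneticMap(markers)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = [
        {"marker": m.name, "chromosome": m.chromosome, "position_cM": m.position}
        for chrom in gmap.chromosomes()
        for m in gmap.markers_on(chrom)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    """Segments table with a parsed ``segment`` object column appended."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty segments table")
    _check_header(df, ["line_id", "donor", "chromosome", "segment_notation"], path)
    if df["line_id"].duplicated().any():
        dups = sorted(df.loc[df["line_id"].duplicated(), "line_id"].unique())
        raise ValueError(f"{path}: duplicate line_id(s) {dups}")
    segs = []
    for i, row in df.iterrows():
        try:
            segs.append(
                parse_segment_notation(str(row["segment_notation"]), int(row["chromosome"]))
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    df = df.copy()
    df["segment"] = segs
    return df


def segments_dict(df: pd.DataFrame) -> dict[str, SubstitutedSegment]:
    return dict(zip(df["line_id"].astype(str), df["segment"]))


def write_segments(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "segment" in out.columns:
        out["segment_notation"] = [format_segment_notation(s) for s in out["segment"]]
        out = out.drop(columns=["segment"])
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty phenotype file")
    _check_header(df, ["line_id", "year", "plant_id", "days_to_heading"], path)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, index=False)


def read_fasta(path, gene: Optional[str] = None) -> list[AlleleSequence]:
    """FASTA records as :class:`AlleleSequence`; ids of the form ``gene|line``
    are split, otherwise ``gene`` (or the record id) labels the gene."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out = []
    for rec in records:
        if not len(rec.seq):
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        if "|" in rec.id:
            g, line = rec.id.split("|", 1)
        else:
            g, line = gene or rec.id, rec.id
        out.append(AlleleSequence(gene=g, line_id=line, seq=str(rec.seq)))
    return out


def write_fasta(alleles: Sequence[AlleleSequence], path) -> None:
    records = [
        SeqRecord(Seq(a.seq), id=f"{a.gene}|{a.line_id}", description="")
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


def variants_to_vcf_like(report: VariantReport) -> pd.DataFrame:
    """Minimal VCF-like table: CHROM = gene, 1-based POS, REF, ALT.

    Indels are emitted VCF-style with the anchoring reference base included
    (POS of a deletion is the base before the deleted run when one exists).
    """
    rows = []
    for v in report.variants:
        if v.kind == "snp":
            rows.append((report.gene, v.ref_start, v.ref_allele, v.alt_allele))
        elif v.kind == "deletion":
            rows.append((report.gene, max(v.ref_start - 1, 1), "." + v.ref_allele, "."))
        else:
            rows.append((report.gene, v.ref_start, ".", "." + v.alt_allele))
    return pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT"])


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML."""

    map_path: str = ""
    segments_path: str = ""
    phenotypes_path: str = ""
    allele_fastas: list[str] = field(default_factory=list)  # ref/alt pairs per file
    control_line: str = "HJX74"
    trait_code: str = "HD"
    alpha: float = 0.01
    mc_draws: int = 100_000
    seed: int = 0
    decimals: int = 2
    align_match: float = 2.0
    align_mismatch: float = -3.0
    align_gap_open: float = -8.0
    align_gap_extend: float = -1.0
    permissive: bool = False

    @property
    def align_params(self) -> AlignParams:
        return AlignParams(
            match=self.align_match,
            mismatch=self.align_mismatch,
            gap_open=self.align_gap_open,
            gap_extend=self.align_gap_extend,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, serializable to JSON/TSV."""

    summaries: pd.DataFrame
    dunnett: pd.DataFrame
    qtls: list[QTLInterval]
    effects: pd.DataFrame
    variant_reports: list[VariantReport]
    consequences: dict[str, ProteinConsequence]
    inconsistencies: list[str]
    config: RunConfig

    def to_json_dict(self) -> dict:
        d = self.config.decimals
        return {
            "config": dataclasses.asdict(self.config),
            "line_summaries": self.summaries.round(d).to_dict(orient="records"),
            "dunnett": self.dunnett.to_dict(orient="records"),
            "qtls": [
                {
                    "name": q.name,
                    "chromosome": q.chromosome,
                    "start_cM": round_report(q.interval.start, d),
                    "end_cM": round_report(q.interval.end, d),
                    "length_cM": round_report(q.length, d),
                    "notation": q.delimiting_notation,
                }
                for q in self.qtls
            ],
            "effects": [
                {
                    k: (round_report(v, d) if isinstance(v, float) else v)
                    for k, v in row.items()
                }
                for row in self.effects.to_dict(orient="records")
            ],
            "variants": [
                {
                    "gene": r.gene,
                    "ref_line": r.ref_line,
                    "alt_line": r.alt_line,
                    "n_snps": r.n_snps,
                    "n_insertions": r.n_insertions,
                    "n_deletions": r.n_deletions,
                    "total_deleted_nt": r.total_deleted_nt,
                    "total_inserted_nt": r.total_inserted_nt,
                    "identity": round(r.alignment_identity, 4),
                    "records": [dataclasses.asdict(v) for v in r.variants],
                }
                for r in self.variant_reports
            ],
            "protein_consequences": {
                g: dataclasses.asdict(c) for g, c in self.consequences.items()
            },
            "inconsistencies": self.inconsistencies,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        d = self.config.decimals
        self.effects.assign(
            **{
                c: self.effects[c].map(lambda x: round_report(x, d))
                for c in self.effects.columns
                if self.effects[c].dtype.kind == "f"
            }
        ).to_csv(out / "effects.tsv", sep="\t", index=False)
        if self.variant_reports:
            pd.concat(
                [variants_to_vcf_like(r) for r in self.variant_reports]
            ).to_csv(out / "variants.tsv", sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> AnalysisReport:
    """Full analysis: per-year Dunnett screen, per-chromosome substitution
    mapping, allelic effects against the control, and (optionally) allele
    CDS comparisons for each supplied FASTA.

    Inconsistencies (e.g. presence calls admitting no QTL interval) are
    collected and raised unless ``cfg.permissive``.
    """
    gmap = read_genetic_map(cfg.map_path)
    seg_df = read_segments(cfg.segments_path)
    segments = segments_dict(seg_df)
    pheno = read_phenotypes(cfg.phenotypes_path)

    summaries = pd.DataFrame([dataclasses.asdict(s) for s in summarize_lines(pheno)])
    mean_by_line_year = {
        (r["line_id"], r["year"]): r["mean"] for r in summaries.to_dict(orient="records")
    }

    dunnett_rows = []
    inconsistencies: list[str] = []
    qtls: list[QTLInterval] = []
    effect_rows = []
    for year in pheno.years():
        results = dunnett_test(
            pheno,
            cfg.control_line,
            alpha=cfg.alpha,
            mc_draws=cfg.mc_draws,
            seed=cfg.seed,
            year=year,
        )
        dunnett_rows.extend(dataclasses.asdict(r) for r in results)
        calls = call_qtl_presence(results, cfg.alpha)
        recipient_mean = mean_by_line_year[(cfg.control_line, year)]

        by_chrom: dict[int, dict[str, SubstitutedSegment]] = {}
        for line, seg in segments.items():
            if line in calls:
                by_chrom.setdefault(seg.chromosome, {})[line] = seg
        for chrom in sorted(by_chrom):
            chrom_segs = by_chrom[chrom]
            chrom_calls = {l: calls[l] for l in chrom_segs}
            if not any(chrom_calls.values()):
                continue
            try:
                mapped = map_qtl(chrom_segs, chrom_calls, gmap, cfg.trait_code)
            except ValueError as exc:
                inconsistencies.append(f"year {year}, chromosome {chrom}: {exc}")
                continue
            for q in mapped:
                if all(q.name != p.name for p in qtls):
                    qtls.append(q)
            positives = sorted(l for l, c in chrom_calls.items() if c)
            for line in positives:
                eff = additive_effect(mean_by_line_year[(line, year)], recipient_mean)
                effect_rows.append(
                    {
                        "line_id": line,
                        "year": year,
                        "chromosome": chrom,
                        "qtl": mapped[0].name if len(mapped) == 1 else "/".join(q.name for q in mapped),
                        "days_to_heading": mean_by_line_year[(line, year)],
                        "additive_effect": eff,
                        "additive_contribution": additive_contribution(eff, recipient_mean),
                    }
                )

    variant_reports = []
    consequences = {}
    for fasta in cfg.allele_fastas:
        alleles = read_fasta(fasta)
        if len(alleles) != 2:
            raise ValueError(f"{fasta}: expected exactly 2 records (ref, alt), got {len(alleles)}")
        ref, alt = alleles
        variant_reports.append(compare_alleles(ref, alt, cfg.align_params))
        consequences[ref.gene] = protein_consequence(ref, alt, cfg.align_params)

    report = AnalysisReport(
        summaries=summaries,
        dunnett=pd.DataFrame(dunnett_rows),
        qtls=qtls,
        effects=pd.DataFrame(effect_rows),
        variant_reports=variant_reports,
        consequences=consequences,
        inconsistencies=inconsistencies,
        config=cfg,
    )
    if inconsistencies and not cfg.permissive:
        raise RuntimeError("; ".join(inconsistencies))
    return report
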
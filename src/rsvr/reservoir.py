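"""The relational schema, build procedure and query layer.

A reservoir is a single-file SQLite database holding the non-reference
genotypes of rare variants only, alongside variant annotations (PMAF,
CADD-like scores, consequence bitmasks), transcript models, sample
metadata, phenotype codes and case sets.  Restricting storage to variants
whose population MAFs are likely below 0.1% keeps the genotype table about
two orders of magnitude smaller than a dense representation.

Build order (merged-VCF mode): extract PASSing records, split
multiallelics, normalize, encode RSVR IDs, load genotypes into a temporary
table, delete internally common variants (cohort MAF >= 0.002 by default),
annotate PMAF and delete score-0 variants, attach pathogenicity scores,
assign consequences against the transcript set, then index.  gVCF mode
additionally drops almost-surely-common variants (binomial test on a
seeded subsample) and sites with a low quality pass rate before loading.

Every build emits a JSON-able report of per-stage record counts so each
filter is testable, and identical inputs plus seed rebuild byte-identical
table contents.
"""

from __future__ import annotations

import json
import logging
import sqlite3
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rsvr import annotation as ann
from rsvr import codec
from rsvr.consequence import TranscriptModel, assign_consequences, load_transcripts

__all__ = [
    "SCHEMA",
    "BuildConfig",
    "build_reservoir",
    "connect",
    "query_gene_variants",
    "classify_participants",
]

logger = logging.getLogger(__name__)

SCHEMA = """
CREATE TABLE VARIANT (
    rsvr_id INTEGER PRIMARY KEY,
    pmaf INTEGER,
    cadd REAL,
    median_gq REAL,
    is_snv INTEGER NOT NULL
);
CREATE TABLE VARIANT_OVERFLOW (
    rsvr_id INTEGER PRIMARY KEY,
    chrom_code INTEGER NOT NULL,
    pos INTEGER NOT NULL,
    ref TEXT NOT NULL,
    alt TEXT NOT NULL
);
CREATE TABLE GENOTYPE (
    sample_id TEXT NOT NULL,
    rsvr_id INTEGER NOT NULL,
    allele_count INTEGER NOT NULL CHECK (allele_count IN (1, 2))
);
CREATE TABLE CONSEQUENCE (
    rsvr_id INTEGER NOT NULL,
    transcript_id TEXT NOT NULL,
    csq INTEGER NOT NULL,
    loftee TEXT
);
CREATE TABLE SAMPLE (
    sample_id TEXT PRIMARY KEY,
    sex TEXT,
    family_id TEXT NOT NULL,
    unrelated INTEGER NOT NULL,
    ancestry TEXT,
    affected INTEGER
);
CREATE TABLE GENE (
    gene_id TEXT PRIMARY KEY,
    biotype TEXT
);
CREATE TABLE TX (
    transcript_id TEXT PRIMARY KEY,
    gene_id TEXT NOT NULL,
    chrom TEXT NOT NULL,
    strand TEXT NOT NULL,
    biotype TEXT,
    canonical INTEGER NOT NULL
);
CREATE TABLE FEATURE (
    transcript_id TEXT NOT NULL,
    feature_type TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL
);
CREATE TABLE PHENOTYPE (
    code TEXT PRIMARY KEY,
    description TEXT
);
CREATE TABLE SAMPLE_PHENOTYPE (
    sample_id TEXT NOT NULL,
    code TEXT NOT NULL
);
CREATE TABLE CASE_SET (
    name TEXT NOT NULL,
    level TEXT NOT NULL CHECK (level IN ('specific_disease', 'sub_group')),
    disease_group TEXT,
    sample_id TEXT NOT NULL
);
"""

_INDICES = """
CREATE INDEX idx_genotype_rsvr ON GENOTYPE (rsvr_id);
CREATE INDEX idx_genotype_sample ON GENOTYPE (sample_id);
CREATE INDEX idx_consequence_rsvr ON CONSEQUENCE (rsvr_id);
CREATE INDEX idx_consequence_tx ON CONSEQUENCE (transcript_id);
CREATE INDEX idx_tx_gene ON TX (gene_id);
CREATE INDEX idx_case_set_name ON CASE_SET (name);
"""


@dataclass
class BuildConfig:
    """Parameters of a reservoir build; the seed governs gVCF subsampling."""

    input_mode: str = "merged_vcf"  # or "gvcf_set"
    internal_maf_threshold: float = 0.002
    depth_pass_threshold: float = 0.9
    subsample_size: int = 10
    require_consequence: bool = True
    delete_pmaf_zero: bool = True
    seed: int = 0
    error_tolerance: int = 100

    def __post_init__(self) -> None:
        if self.input_mode not in {"merged_vcf", "gvcf_set"}:
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if not 0 < self.internal_maf_threshold < 1:
            raise ValueError("internal MAF threshold must be in (0, 1)")


def connect(db_path: str | Path) -> sqlite3.Connection:
    conn = sqlite3.connect(str(db_path))
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def _iter_vcf_records(vcf_path: str):
    """Yield (chrom, pos, ref, alt, alt_index, record) for each split
    biallelic record of a VCF, via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    for rec in vcf:
        yield rec, samples


def _genotype_allele_counts(rec, alt_index: int) -> list[int]:
    """Per-sample count of the given alternate allele (allele number
    ``alt_index + 1``); missing calls count 0."""
    counts = []
    for gt in rec.genotypes:
        alleles = gt[:-1]
        counts.append(sum(1 for a in alleles if a == alt_index + 1))
    return counts


def build_reservoir(
    db_path: str | Path,
    vcf_input: str | Sequence[str],
    sample_sheet: pd.DataFrame | str,
    transcripts: Sequence[TranscriptModel] | str,
    genome,
    population_counts: Mapping[int, list] | str | None = None,
    cadd_scores: Mapping[int, float] | str | None = None,
    cfg: BuildConfig | None = None,
    case_sets: pd.DataFrame | str | None = None,
    chrx_nonpar: tuple[int, int] | None = None,
) -> dict:
    """Build a reservoir database file; returns the build report.

    ``vcf_input`` is one merged VCF path (``merged_vcf`` mode) or a list of
    single-sample VCF paths (``gvcf_set`` mode).  Annotation sources accept
    in-memory mappings or TSV paths.
    """
    cfg = cfg or BuildConfig()
    if isinstance(sample_sheet, str):
        sample_sheet = pd.read_csv(sample_sheet, sep="\t")
    if isinstance(transcripts, str):
        transcripts = load_transcripts(transcripts)
    if isinstance(population_counts, str):
        population_counts = ann.load_population_counts(population_counts)
    population_counts = population_counts or {}
    if isinstance(cadd_scores, str):
        cadd_df = pd.read_csv(cadd_scores, sep="\t")
        cadd_scores = dict(zip(cadd_df["rsvr_id"].astype(int), cadd_df["cadd"]))
    cadd_scores = cadd_scores or {}
    if isinstance(case_sets, str):
        case_sets = pd.read_csv(case_sets, sep="\t")
    if isinstance(genome, str):
        import pyfaidx

        genome = pyfaidx.Fasta(genome)

    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()
    conn = connect(db_path)
    conn.executescript(SCHEMA)
    report: dict = {"config": {"mode": cfg.input_mode, "seed": cfg.seed}, "stages": {}}

    if cfg.input_mode == "merged_vcf":
        variants, genotypes, errors, gq_medians = _extract_merged(vcf_input, cfg)
    else:
        variants, genotypes, errors = _extract_gvcfs(list(vcf_input), cfg, report)
        gq_medians = {}
    report["stages"]["extracted_variants"] = len(variants)
    report["stages"]["skipped_records"] = errors
    if errors > cfg.error_tolerance:
        raise ValueError(f"{errors} unparseable records exceed tolerance")

    # temporary genotype load, then the internal allele-frequency DELETE
    gt_rows = [
        (sample, vid, count)
        for vid, carriers in sorted(genotypes.items())
        for sample, count in sorted(carriers.items())
    ]
    gt_df = pd.DataFrame(gt_rows, columns=["sample_id", "rsvr_id", "allele_count"])
    n_samples = len(sample_sheet)
    common = ann.internal_af_filter(gt_df, n_samples, cfg.internal_maf_threshold)
    for vid in common:
        variants.pop(vid, None)
        genotypes.pop(vid, None)
    report["stages"]["after_internal_af"] = len(variants)

    # PMAF annotation; optionally drop score-0 variants
    pmaf: dict[int, int] = {}
    for vid, v in variants.items():
        nonpar = (
            chrx_nonpar is not None
            and v.chrom_code == 23
            and chrx_nonpar[0] <= v.pos <= chrx_nonpar[1]
        )
        pmaf[vid] = ann.pmaf_score(population_counts.get(vid, []), chrx_nonpar=nonpar)
    if cfg.delete_pmaf_zero:
        for vid in [v for v, s in pmaf.items() if s == 0]:
            variants.pop(vid)
            genotypes.pop(vid, None)
    report["stages"]["after_pmaf_filter"] = len(variants)

    # consequence annotation
    csq_rows = []
    for vid, v in sorted(variants.items()):
        for t in transcripts:
            terms = assign_consequences(v, t, genome)
            if terms:
                csq_rows.append((vid, t.transcript_id, codec.encode_csq(terms), None))
    annotated_ids = {row[0] for row in csq_rows}
    if cfg.require_consequence:
        for vid in [v for v in variants if v not in annotated_ids]:
            variants.pop(vid)
            genotypes.pop(vid, None)
    report["stages"]["after_consequence_filter"] = len(variants)

    # final loads
    median_gq = {vid: gq for vid, gq in gq_medians.items() if vid in variants}
    conn.executemany(
        "INSERT INTO VARIANT VALUES (?, ?, ?, ?, ?)",
        [
            (
                vid,
                pmaf[vid],
                cadd_scores.get(vid),
                median_gq.get(vid),
                int(v.is_snv),
            )
            for vid, v in sorted(variants.items())
        ],
    )
    conn.executemany(
        "INSERT INTO VARIANT_OVERFLOW VALUES (?, ?, ?, ?, ?)",
        [
            (vid, v.chrom_code, v.pos, v.ref, v.alt)
            for vid, v in sorted(variants.items())
            if not codec.is_lossless(v)
        ],
    )
    conn.executemany(
        "INSERT INTO GENOTYPE VALUES (?, ?, ?)",
        [
            (sample, vid, count)
            for vid, carriers in sorted(genotypes.items())
            for sample, count in sorted(carriers.items())
        ],
    )
    conn.executemany(
        "INSERT INTO CONSEQUENCE VALUES (?, ?, ?, ?)",
        [r for r in csq_rows if r[0] in variants],
    )
    _load_samples(conn, sample_sheet)
    _load_transcript_tables(conn, transcripts)
    if case_sets is not None:
        conn.executemany(
            "INSERT INTO CASE_SET VALUES (?, ?, ?, ?)",
            [
                (r.case_set, r.level, getattr(r, "disease_group", None), r.sample_id)
                for r in case_sets.itertuples(index=False)
            ],
        )
    conn.executescript(_INDICES)
    report["stages"]["variants"] = len(variants)
    report["stages"]["genotypes"] = sum(len(c) for c in genotypes.values())
    report["stages"]["consequences"] = sum(1 for r in csq_rows if r[0] in variants)
    conn.execute("CREATE TABLE BUILD_REPORT (report TEXT)")
    conn.execute("INSERT INTO BUILD_REPORT VALUES (?)", (json.dumps(report, sort_keys=True),))
    conn.commit()
    conn.close()
    return report


def _extract_merged(vcf_path: str, cfg: BuildConfig):
    variants: dict[int, codec.NormalizedVariant] = {}
    genotypes: dict[int, dict[str, int]] = {}
    gq_store: dict[int, list] = {}
    errors = 0
    for rec, samples in _iter_vcf_records(vcf_path):
        if rec.FILTER is not None:  # cyvcf2: None means PASS
            continue
        try:
            gq = rec.format("GQ")
        except Exception:
            gq = None
        for alt_index, alt in enumerate(rec.ALT):
            try:
                v = codec.normalize_variant(
                    codec.chrom_code(rec.CHROM), rec.POS, rec.REF, alt
                )
                vid = codec.encode_rsvr(v)
            except (ValueError, OverflowError) as exc:
                logger.warning("skipping %s:%s %s>%s: %s", rec.CHROM, rec.POS, rec.REF, alt, exc)
                errors += 1
                continue
            counts = _genotype_allele_counts(rec, alt_index)
            carriers = {
                samples[i]: min(c, 2) for i, c in enumerate(counts) if c > 0
            }
            if not carriers:
                continue
            variants[vid] = v
            store = genotypes.setdefault(vid, {})
            for s, c in carriers.items():
                store[s] = max(store.get(s, 0), c)
            if gq is not None:
                gq_store.setdefault(vid, []).extend(
                    float(gq[i][0]) for i, c in enumerate(counts) if c > 0
                )
    gq_medians = {
        vid: statistics.median(vals) for vid, vals in gq_store.items() if vals
    }
    return variants, genotypes, errors, gq_medians


def _extract_gvcfs(paths: list[str], cfg: BuildConfig, report: dict):
    """Single-sample mode: tabulate almost-surely-common variants and depth
    pass rates on a seeded subsample, then read every file."""
    rng = np.random.default_rng(cfg.seed)
    k = min(cfg.subsample_size, len(paths))
    subsample = sorted(rng.choice(len(paths), size=k, replace=False).tolist())
    sub_counts: dict[int, list[int]] = {}
    sub_records = []
    for idx in subsample:
        records = []
        for rec, samples in _iter_vcf_records(paths[idx]):
            passes = rec.FILTER is None
            records.append((rec.POS, rec.POS + len(rec.REF) - 1, passes))
            if not passes:
                continue
            for alt_index, alt in enumerate(rec.ALT):
                try:
                    v = codec.normalize_variant(
                        codec.chrom_code(rec.CHROM), rec.POS, rec.REF, alt
                    )
                    vid = codec.encode_rsvr(v)
                except (ValueError, OverflowError):
                    continue
                ac = sum(_genotype_allele_counts(rec, alt_index))
                entry = sub_counts.setdefault(vid, [0, 0])
                entry[0] += ac
        sub_records.append(records)
    for entry in sub_counts.values():
        entry[1] = 2 * k
    common = ann.tabulate_common({v: tuple(c) for v, c in sub_counts.items()})
    report["stages"]["tabulated_common"] = len(common)

    variants: dict[int, codec.NormalizedVariant] = {}
    genotypes: dict[int, dict[str, int]] = {}
    errors = 0
    positions_needed: dict[int, tuple] = {}
    staged = []
    for path in paths:
        for rec, samples in _iter_vcf_records(path):
            if rec.FILTER is not None:
                continue
            for alt_index, alt in enumerate(rec.ALT):
                try:
                    v = codec.normalize_variant(
                        codec.chrom_code(rec.CHROM), rec.POS, rec.REF, alt
                    )
                    vid = codec.encode_rsvr(v)
                except (ValueError, OverflowError):
                    errors += 1
                    continue
                if vid in common:
                    continue
                ac = sum(_genotype_allele_counts(rec, alt_index))
                if ac == 0:
                    continue
                staged.append((vid, v, samples[0], min(ac, 2), rec.POS))
                positions_needed[vid] = rec.POS
    pass_rates = ann.depth_pass_rate(sub_records, set(positions_needed.values()))
    low_depth = {
        vid
        for vid, pos in positions_needed.items()
        if pass_rates.get(pos, 0.0) < cfg.depth_pass_threshold
    }
    report["stages"]["low_depth_variants"] = len(low_depth)
    for vid, v, sample, ac, _pos in staged:
        if vid in low_depth:
            continue
        variants[vid] = v
        genotypes.setdefault(vid, {})[sample] = ac
    return variants, genotypes, errors


def _load_samples(conn: sqlite3.Connection, sheet: pd.DataFrame) -> None:
    required = {"sample_id", "sex", "family_id", "unrelated"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    conn.executemany(
        "INSERT INTO SAMPLE VALUES (?, ?, ?, ?, ?, ?)",
        [
            (
                r.sample_id,
                r.sex,
                r.family_id,
                int(r.unrelated),
                getattr(r, "ancestry", None),
                int(getattr(r, "affected", 0)),
            )
            for r in sheet.itertuples(index=False)
        ],
    )


def _load_transcript_tables(
    conn: sqlite3.Connection, transcripts: Sequence[TranscriptModel]
) -> None:
    genes = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, t.biotype)
        conn.execute(
            "INSERT INTO TX VALUES (?, ?, ?, ?, ?, ?)",
            (t.transcript_id, t.gene_id, t.chrom, t.strand, t.biotype, int(t.canonical)),
        )
        for s, e in t.exons:
            conn.execute(
                "INSERT INTO FEATURE VALUES (?, 'exon', ?, ?)", (t.transcript_id, s, e)
            )
        for s, e in t.cds:
            conn.execute(
                "INSERT INTO FEATURE VALUES (?, 'CDS', ?, ?)", (t.transcript_id, s, e)
            )
    conn.executemany("INSERT INTO GENE VALUES (?, ?)", sorted(genes.items()))


def query_gene_variants(
    conn: sqlite3.Connection,
    gene_id: str,
    impact_class: str | None = None,
    pmaf_min: int = 0,
) -> pd.DataFrame:
    """Variants affecting a gene's transcripts, with consequences and scores.

    Rows satisfy ``meets_impact(csq, impact_class)`` (when a class is given)
    and ``pmaf >= pmaf_min``, ordered by RSVR ID.
    """
    known = conn.execute(
        "SELECT COUNT(*) FROM GENE WHERE gene_id = ?", (gene_id,)
    ).fetchone()[0]
    if not known:
        raise KeyError(f"unknown gene {gene_id!r}")
    df = pd.read_sql_query(
        """
        SELECT v.rsvr_id, c.transcript_id, c.csq, c.loftee, v.pmaf, v.cadd,
               v.median_gq, v.is_snv
        FROM VARIANT v
        JOIN CONSEQUENCE c ON c.rsvr_id = v.rsvr_id
        JOIN TX t ON t.transcript_id = c.transcript_id
        WHERE t.gene_id = ? AND v.pmaf >= ?
        ORDER BY v.rsvr_id
        """,
        conn,
        params=(gene_id, pmaf_min),
    )
    if impact_class is not None:
        df = df[df["csq"].map(lambda m: codec.meets_impact(int(m), impact_class))]
    return df.reset_index(drop=True)


def gene_genotypes(conn: sqlite3.Connection, rsvr_ids: Iterable[int]) -> dict[int, dict[str, int]]:
    """Carrier maps for the given variants: rsvr_id -> {sample: allele count}."""
    out: dict[int, dict[str, int]] = {}
    ids = list(rsvr_ids)
    if not ids:
        return out
    marks = ",".join("?" * len(ids))
    for sample, vid, count in conn.execute(
        f"SELECT sample_id, rsvr_id, allele_count FROM GENOTYPE WHERE rsvr_id IN ({marks})",
        ids,
    ):
        out.setdefault(int(vid), {})[sample] = int(count)
    return out


def classify_participants(conn: sqlite3.Connection, case_set: str) -> dict[str, str]:
    """Label every sample as case_proband / case_relative / control /
    control_relative for one case set."""
    members = {
        row[0]
        for row in conn.execute(
            "SELECT sample_id FROM CASE_SET WHERE name = ?", (case_set,)
        )
    }
    if not members:
        raise KeyError(f"unknown or empty case set {case_set!r}")
    labels = {}
    case_families = set()
    samples = conn.execute(
        "SELECT sample_id, family_id, unrelated FROM SAMPLE"
    ).fetchall()
    family_of = {s: f for s, f, _ in samples}
    case_families = {family_of[s] for s in members if s in family_of}
    for sample, family, unrelated in samples:
        if sample in members:
            labels[sample] = "case_proband"
        elif family in case_families:
            labels[sample] = "case_relative"
        elif unrelated:
            labels[sample] = "control"
        else:
            labels[sample] = "control_relative"
    return labels
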
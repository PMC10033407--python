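"""Seeded generation of every input the pipeline consumes.

Produces a toy reference (FASTA + GTF), pedigreed cohorts with planted
dominant or recessive etiologies at configurable penetrance (merged VCF,
PED, sample sheet, case sets, truth table), population allele-count and
pathogenicity-score references, gene panels, and a small ontology with
per-family term annotations containing a planted phenotypically similar
family cluster.  Identical seeds produce byte-identical outputs.

Each gene occupies a 1,000-base block of chromosome 1 with the layout

    exons  [10,30) [40,60) [70,90)      (block-relative)
    CDS    [20,30) [40,60) [70,82)      = ATG + 12x GAA + TAA

so stop-gained, missense and 5' UTR variants can be planted at known
positions.  Background variants draw their frequencies from a log-uniform
spectrum on [min_maf, max_maf], approximating the neutral 1/x density, so
the sub-0.1% stratum holds a small share of non-reference genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from rsvr import codec
from rsvr.codec import NormalizedVariant
from rsvr.consequence import TranscriptModel

__all__ = [
    "PlantedEtiology",
    "SimConfig",
    "SimReference",
    "SimCohort",
    "simulate_reference",
    "simulate_cohort",
    "simulate_annotations",
    "simulate_association_instance",
]

GENE_BLOCK = 1000
_EXONS = ((10, 30), (40, 60), (70, 90))
_CDS = ((20, 30), (40, 60), (70, 82))
_CDS_SEQ = "ATG" + "GAA" * 12 + "TAA"


@dataclass(frozen=True)
class PlantedEtiology:
    gene: str
    moi: str  # dominant | recessive
    variant_class: str  # high | moderate | utr5
    n_pathogenic_variants: int = 3
    penetrance: float = 0.95
    phenocopy_rate: float = 0.001
    case_set: str = "Planted disease"
    disease_group: str = "Planted group"
    n_carrier_families: int = 10
    #: recessive only: families where the allele segregates in healthy
    #: heterozygous form, as it would in a real population; without them a
    #: recessive signal is indistinguishable from a dominant one
    n_het_carrier_families: int = 8


@dataclass
class SimConfig:
    seed: int = 0
    n_families: int = 100
    n_genes: int = 3
    n_background_variants: int = 60
    min_maf: float = 0.0005
    max_maf: float = 0.05
    etiologies: list[PlantedEtiology] = field(default_factory=list)
    cluster_size: int = 4  # families in the planted phenotype cluster

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if not 0 < self.min_maf < self.max_maf < 1:
            raise ValueError("MAF spectrum bounds must satisfy 0 < min < max < 1")


@dataclass
class SimReference:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    fasta_path: Path | None = None
    gtf_path: Path | None = None

    def gene_index(self, gene: str) -> int:
        return [t.gene_id for t in self.transcripts].index(gene)


@dataclass
class SimCohort:
    samples: pd.DataFrame  # sample sheet
    pedigree: pd.DataFrame  # PED columns
    genotypes: dict[int, dict[str, int]]
    variants: dict[int, NormalizedVariant]
    case_sets: pd.DataFrame
    truth: pd.DataFrame  # planted variants and configuration carriers
    background_freq: dict[int, float]
    vcf_path: Path | None = None


def simulate_reference(cfg: SimConfig, outdir: str | Path | None = None) -> SimReference:
    """Toy genome and transcript models; optionally written as FASTA + GTF."""
    rng = np.random.default_rng(cfg.seed)
    length = cfg.n_genes * GENE_BLOCK
    seq = rng.choice(list("ACGT"), size=length)
    transcripts = []
    for g in range(cfg.n_genes):
        off = g * GENE_BLOCK
        strand = "+"
        seq[off + 20 : off + 30] = list(_CDS_SEQ[0:10])
        seq[off + 40 : off + 60] = list(_CDS_SEQ[10:30])
        seq[off + 70 : off + 82] = list(_CDS_SEQ[30:42])
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{g:03d}",
                gene_id=f"GENE{g:03d}",
                chrom="1",
                strand=strand,
                exons=tuple((off + s, off + e) for s, e in _EXONS),
                cds=tuple((off + s, off + e) for s, e in _CDS),
            )
        )
    genome = {"1": "".join(seq)}
    ref = SimReference(genome=genome, transcripts=transcripts)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "reference.fa"
        with fasta.open("w") as fh:
            fh.write(">1\n")
            for i in range(0, length, 60):
                fh.write(genome["1"][i : i + 60] + "\n")
        gtf = outdir / "transcripts.gtf"
        with gtf.open("w") as fh:
            for t in transcripts:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "protein_coding";'
                )
                for s, e in t.exons:
                    fh.write(f"1\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
                for s, e in t.cds:
                    fh.write(f"1\tsim\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
        ref.fasta_path = fasta
        ref.gtf_path = gtf
    return ref


def planted_variant_sites(
    ref: SimReference, gene: str, variant_class: str, k: int
) -> list[NormalizedVariant]:
    """``k`` distinct variants of the requested impact class inside a gene."""
    g = ref.gene_index(gene)
    off = g * GENE_BLOCK
    out = []
    if variant_class == "high":
        # G>T at the first base of successive GAA codons makes TAA
        for codon in range(1, 13):
            cds_idx = 3 * codon
            out.append(NormalizedVariant(1, off + _cds_to_genomic(cds_idx) + 1, "G", "T"))
    elif variant_class == "moderate":
        # A>C at the second base of successive GAA codons makes GCA (Glu->Ala)
        for codon in range(1, 13):
            cds_idx = 3 * codon + 1
            out.append(NormalizedVariant(1, off + _cds_to_genomic(cds_idx) + 1, "A", "C"))
    elif variant_class == "utr5":
        for pos0 in range(10, 20):
            base = ref.genome["1"][off + pos0]
            alt = "A" if base != "A" else "C"
            out.append(NormalizedVariant(1, off + pos0 + 1, base, alt))
    else:
        raise ValueError(f"unknown variant class {variant_class!r}")
    if k > len(out):
        raise ValueError(f"cannot plant {k} {variant_class} variants in one gene")
    return out[:k]


def _cds_to_genomic(cds_idx: int) -> int:
    if cds_idx < 10:
        return 20 + cds_idx
    if cds_idx < 30:
        return 40 + cds_idx - 10
    return 70 + cds_idx - 30


def simulate_cohort(
    cfg: SimConfig, ref: SimReference, outdir: str | Path | None = None
) -> SimCohort:
    """Trio pedigrees with Mendelian transmission and planted etiologies."""
    rng = np.random.default_rng(cfg.seed + 1)
    for et in cfg.etiologies:
        if et.moi == "recessive" and et.n_pathogenic_variants < 1:
            raise ValueError("recessive etiology needs at least one variant")
        if et.n_carrier_families > cfg.n_families:
            raise ValueError("more carrier families than families")

    families = [f"F{i:04d}" for i in range(cfg.n_families)]
    rows = []
    for fam in families:
        father, mother, child = f"{fam}_fa", f"{fam}_mo", f"{fam}_ch"
        rows.append((fam, father, "0", "0", 1))
        rows.append((fam, mother, "0", "0", 2))
        rows.append((fam, child, father, mother, int(rng.integers(1, 3))))
    ped = pd.DataFrame(rows, columns=["family_id", "sample_id", "father", "mother", "sex"])
    samples = list(ped["sample_id"])
    sample_idx = {s: i for i, s in enumerate(samples)}
    n = len(samples)

    variants: dict[int, NormalizedVariant] = {}
    genotypes = np.zeros((n, 0), dtype=np.int8)
    geno_cols: list[np.ndarray] = []
    vids: list[int] = []
    background_freq: dict[int, float] = {}

    # background spectrum: log-uniform frequencies (approximate 1/x density)
    occupied = set()
    n_bg = 0
    while n_bg < cfg.n_background_variants:
        pos0 = int(rng.integers(0, len(ref.genome["1"])))
        if pos0 in occupied:
            continue
        occupied.add(pos0)
        base = ref.genome["1"][pos0]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == base:
            continue
        v = NormalizedVariant(1, pos0 + 1, base, alt)
        vid = codec.encode_rsvr(v)
        if vid in variants:
            continue
        freq = float(
            cfg.min_maf * (cfg.max_maf / cfg.min_maf) ** rng.random()
        )
        col = np.zeros(n, dtype=np.int8)
        for fam in families:
            fa, mo, ch = sample_idx[f"{fam}_fa"], sample_idx[f"{fam}_mo"], sample_idx[f"{fam}_ch"]
            g_fa = int(rng.random() < freq) + int(rng.random() < freq)
            g_mo = int(rng.random() < freq) + int(rng.random() < freq)
            transmit_fa = g_fa == 2 or (g_fa == 1 and rng.random() < 0.5)
            transmit_mo = g_mo == 2 or (g_mo == 1 and rng.random() < 0.5)
            col[fa], col[mo] = g_fa, g_mo
            col[ch] = int(transmit_fa) + int(transmit_mo)
        variants[vid] = v
        vids.append(vid)
        geno_cols.append(col)
        background_freq[vid] = freq
        n_bg += 1

    # planted etiologies
    truth_rows = []
    config_carrier: dict[str, set[str]] = {}
    for et in cfg.etiologies:
        sites = planted_variant_sites(ref, et.gene, et.variant_class, et.n_pathogenic_variants)
        site_ids = []
        for v in sites:
            vid = codec.encode_rsvr(v)
            if vid not in variants:
                variants[vid] = v
                vids.append(vid)
                geno_cols.append(np.zeros(n, dtype=np.int8))
            site_ids.append(vid)
        carrier_fams = [
            families[i]
            for i in sorted(
                rng.choice(cfg.n_families, size=et.n_carrier_families, replace=False)
            )
        ]
        carriers: set[str] = set()
        for fam_i, fam in enumerate(carrier_fams):
            vid = site_ids[fam_i % len(site_ids)]
            j = vids.index(vid)
            fa, mo, ch = (
                sample_idx[f"{fam}_fa"],
                sample_idx[f"{fam}_mo"],
                sample_idx[f"{fam}_ch"],
            )
            if et.moi == "dominant":
                # one carrier parent transmits to the child
                parent = fa if rng.random() < 0.5 else mo
                geno_cols[j][parent] = max(geno_cols[j][parent], 1)
                geno_cols[j][ch] = max(geno_cols[j][ch], 1)
                carriers |= {samples[parent], samples[ch]}
            else:
                # both parents heterozygous, child homozygous
                geno_cols[j][fa] = max(geno_cols[j][fa], 1)
                geno_cols[j][mo] = max(geno_cols[j][mo], 1)
                geno_cols[j][ch] = 2
                carriers.add(samples[ch])
        if et.moi == "recessive" and et.n_het_carrier_families:
            remaining = [f for f in families if f not in set(carrier_fams)]
            n_het = min(et.n_het_carrier_families, len(remaining))
            het_fams = [
                remaining[i]
                for i in sorted(rng.choice(len(remaining), size=n_het, replace=False))
            ]
            for fam_i, fam in enumerate(het_fams):
                vid = site_ids[fam_i % len(site_ids)]
                j = vids.index(vid)
                parent = sample_idx[f"{fam}_fa" if rng.random() < 0.5 else f"{fam}_mo"]
                geno_cols[j][parent] = max(geno_cols[j][parent], 1)
                if rng.random() < 0.5:
                    ch = sample_idx[f"{fam}_ch"]
                    geno_cols[j][ch] = max(geno_cols[j][ch], 1)
        config_carrier[et.case_set] = carriers
        for vid in site_ids:
            truth_rows.append(
                {
                    "gene": et.gene,
                    "case_set": et.case_set,
                    "moi": et.moi,
                    "variant_class": et.variant_class,
                    "rsvr_id": vid,
                }
            )

    G = np.column_stack(geno_cols) if geno_cols else np.zeros((n, 0), dtype=np.int8)

    # affection status: configuration carriers are affected with probability
    # f1, everyone else with the phenocopy rate f0
    affected = np.zeros(n, dtype=bool)
    case_rows = []
    for et in cfg.etiologies:
        carriers = config_carrier[et.case_set]
        for s in samples:
            p = et.penetrance if s in carriers else et.phenocopy_rate
            if rng.random() < p:
                affected[sample_idx[s]] = True
                case_rows.append(
                    {
                        "case_set": et.case_set,
                        "level": "specific_disease",
                        "disease_group": et.disease_group,
                        "sample_id": s,
                    }
                )
    case_sets = pd.DataFrame(
        case_rows, columns=["case_set", "level", "disease_group", "sample_id"]
    ).drop_duplicates()

    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "sex": ["male" if x == 1 else "female" for x in ped["sex"]],
            "family_id": list(ped["family_id"]),
            "unrelated": [int(not s.endswith("_ch")) for s in samples],
            "ancestry": "sim",
            "affected": affected.astype(int),
        }
    )

    order = np.argsort(vids)
    genotype_map = {
        int(vids[j]): {
            samples[i]: int(G[i, j]) for i in range(n) if G[i, j] > 0
        }
        for j in order
    }
    cohort = SimCohort(
        samples=sheet,
        pedigree=ped,
        genotypes=genotype_map,
        variants={int(vid): variants[vid] for vid in vids},
        case_sets=case_sets,
        truth=pd.DataFrame(truth_rows),
        background_freq=background_freq,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.vcf_path = _write_vcf(outdir / "cohort.vcf", ref, cohort, samples)
        ped_out = ped.copy()
        ped_out["affected"] = [1 + int(affected[sample_idx[s]]) for s in samples]
        ped_out.to_csv(outdir / "cohort.ped", sep="\t", index=False, header=False)
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        case_sets.to_csv(outdir / "case_sets.tsv", sep="\t", index=False)
        cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return cohort


def _write_vcf(path: Path, ref: SimReference, cohort: SimCohort, samples: list[str]) -> Path:
    """Minimal VCF 4.2 with GT and a constant high GQ."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=1,length={len(ref.genome['1'])}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for vid in sorted(cohort.variants):
        v = cohort.variants[vid]
        carriers = cohort.genotypes.get(vid, {})
        # re-anchor empty alleles on the preceding reference base
        if v.ref and v.alt:
            pos, ref_a, alt_a = v.pos, v.ref, v.alt
        else:
            anchor = ref.genome["1"][v.pos - 2]
            pos, ref_a, alt_a = v.pos - 1, anchor + v.ref, anchor + v.alt
        gts = []
        for s in samples:
            c = carriers.get(s, 0)
            gts.append(("0/0", "0/1", "1/1")[c] + ":99")
        lines.append(
            f"1\t{pos}\t.\t{ref_a}\t{alt_a}\t100\tPASS\t.\tGT:GQ\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def simulate_annotations(
    cfg: SimConfig, ref: SimReference, cohort: SimCohort, outdir: str | Path | None = None
) -> dict:
    """Population counts, CADD-like scores, panels, ontology and family terms.

    Planted pathogenic variants are absent from the population reference
    (PMAF 3); background variants get counts matching their simulated
    frequency.  A cluster of ``cfg.cluster_size`` families receives a
    shared block of specific phenotype terms.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    planted = set(cohort.truth["rsvr_id"]) if len(cohort.truth) else set()
    an = 100_000
    pop_rows = []
    for vid, freq in sorted(cohort.background_freq.items()):
        pop_rows.append(
            {
                "rsvr_id": vid,
                "population": "simpop",
                "ac": int(round(freq * an)),
                "an": an,
            }
        )
    pop_counts = pd.DataFrame(pop_rows, columns=["rsvr_id", "population", "ac", "an"])

    cadd_rows = []
    for vid, v in sorted(cohort.variants.items()):
        if not v.is_snv:
            continue
        score = 25.0 + rng.random() * 10 if vid in planted else float(rng.random() * 40)
        cadd_rows.append({"rsvr_id": vid, "cadd": round(score, 2)})
    cadd = pd.DataFrame(cadd_rows, columns=["rsvr_id", "cadd"])

    panel_rows = []
    for et in cfg.etiologies:
        panel_rows.append(
            {
                "panel": et.case_set,
                "panel_type": "Rare Disease 100K",
                "sub_group": et.disease_group,
                "gene": et.gene,
                "evidence": "green",
                "gene_count": 25,
            }
        )
    panels = pd.DataFrame(
        panel_rows,
        columns=["panel", "panel_type", "sub_group", "gene", "evidence", "gene_count"],
    )

    obo_text, terms_by_branch = _toy_ontology()
    families = sorted(cohort.samples["family_id"].unique())
    cluster = families[: cfg.cluster_size]
    branch_names = sorted(terms_by_branch)
    cluster_branch = branch_names[0]
    term_rows = []
    for fam in families:
        if fam in cluster:
            chosen = terms_by_branch[cluster_branch][:3]
        else:
            branch = branch_names[int(rng.integers(1, len(branch_names)))]
            leaves = terms_by_branch[branch]
            chosen = sorted(
                leaves[i] for i in rng.choice(len(leaves), size=2, replace=False)
            )
        for term in chosen:
            term_rows.append({"family_id": fam, "term_id": term})
    family_terms = pd.DataFrame(term_rows, columns=["family_id", "term_id"])

    out = {
        "population_counts": pop_counts,
        "cadd": cadd,
        "panels": panels,
        "obo": obo_text,
        "family_terms": family_terms,
        "cluster_families": cluster,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pop_counts.to_csv(outdir / "population_counts.tsv", sep="\t", index=False)
        cadd.to_csv(outdir / "cadd.tsv", sep="\t", index=False)
        panels.to_csv(outdir / "panels.tsv", sep="\t", index=False)
        (outdir / "ontology.obo").write_text(obo_text)
        family_terms.to_csv(outdir / "family_terms.tsv", sep="\t", index=False)
    return out


def _toy_ontology() -> tuple[str, dict[str, list[str]]]:
    """A three-level is-a tree: root -> 5 branches -> 6 leaves each."""
    stanzas = ["format-version: 1.2\nontology: simhpo\n"]
    stanzas.append("[Term]\nid: SIM:0000001\nname: phenotypic abnormality\n")
    terms_by_branch: dict[str, list[str]] = {}
    tid = 2
    for b in range(5):
        branch_id = f"SIM:{tid:07d}"
        tid += 1
        stanzas.append(
            f"[Term]\nid: {branch_id}\nname: branch {b}\nis_a: SIM:0000001\n"
        )
        leaves = []
        for _ in range(6):
            leaf_id = f"SIM:{tid:07d}"
            tid += 1
            stanzas.append(
                f"[Term]\nid: {leaf_id}\nname: leaf {leaf_id}\nis_a: {branch_id}\n"
            )
            leaves.append(leaf_id)
        terms_by_branch[branch_id] = leaves
    return "\n".join(stanzas), terms_by_branch


def simulate_association_instance(
    n_cases: int,
    n_controls: int,
    n_pathogenic: int,
    moi: str,
    penetrance: float = 0.95,
    background_rate: float = 0.002,
    n_background_variants: int = 5,
    het_carrier_rate: float = 0.004,
    seed: int = 0,
):
    """Matrix-level cohort with a planted etiology, for calibration studies.

    Draws carrier configurations, assigns case status by penetrance /
    phenocopy, then subsamples to exactly ``n_cases`` cases and
    ``n_controls`` controls.  Returns ``(G, y, pathogenic_column_indices)``.
    """
    rng = np.random.default_rng(seed)
    n_pool = (n_cases + n_controls) * 3
    J = n_pathogenic + n_background_variants
    G = np.zeros((n_pool, J), dtype=np.int8)
    for j in range(n_pathogenic, J):
        G[:, j] = rng.binomial(1, background_rate, n_pool) + rng.binomial(
            1, background_rate, n_pool
        )
    config = np.zeros(n_pool, dtype=bool)
    if n_pathogenic > 0:
        if moi == "recessive":
            # unaffected heterozygous carriers, as segregate in a population;
            # they separate the recessive signal from a dominant reading
            for j in range(n_pathogenic):
                G[:, j] = rng.binomial(1, het_carrier_rate, n_pool)
        # carriers of the pathogenic configuration: ~2 per case-pool thousand
        n_config = max(n_pathogenic * 6, n_pool // 500)
        config_rows = rng.choice(n_pool, size=n_config, replace=False)
        for i, row in enumerate(config_rows):
            j = i % n_pathogenic
            G[row, j] = 1 if moi == "dominant" else 2
        config[config_rows] = True
    phenocopy = n_cases / n_pool  # keeps roughly n_cases affected under the null
    p_case = np.where(config, penetrance, phenocopy)
    y = rng.random(n_pool) < p_case
    case_rows = np.flatnonzero(y)[:n_cases]
    control_rows = np.flatnonzero(~y)[:n_controls]
    rows = np.concatenate([case_rows, control_rows])
    y_out = np.zeros(rows.shape[0], dtype=bool)
    y_out[: case_rows.shape[0]] = True
    return G[rows], y_out, list(range(n_pathogenic))
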
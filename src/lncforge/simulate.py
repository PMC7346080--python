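"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline targets: two groups
of six arrays, log-normal probe intensities on the log2 scale, planted
differentially expressed probes at a stated log2 fold change, planted
lncRNA-mRNA co-expressed pairs built as affine transforms of a shared
profile plus noise, lncRNA loci realising each of the six positional
classes on one synthetic chromosome, KEGG-style gene sets with one set
planted on the DE genes, exponential survival times with a group hazard
ratio, and qPCR Ct values with a planted ddCt shift.

Every generator is driven by ``numpy.random.default_rng`` seeded from the
config, with one fixed stream id per generator, so the same config yields
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, PositionalClass
from .enrichment import GeneSet, write_gmt
from .matrix import GROUP1, GROUP2, ExpressionMatrix

CASSETTE = 400_000          # bp reserved per lncRNA locus on the synthetic chromosome
_GENE_OFFSET = 100_000      # gene body at [offset, offset+10kb) inside its cassette
_GENE_LEN = 10_000

# per-class lncRNA placement inside a cassette, relative to the cassette start
_CLASS_LAYOUT = {
    "exon_sense_overlapping": (100_500, 101_500, "+"),
    "intron_sense_overlapping": (102_000, 103_000, "+"),
    "natural_antisense": (100_500, 101_500, "-"),
    "intronic_antisense": (102_000, 103_000, "-"),
    "bidirectional": (98_500, 99_500, "-"),
    "intergenic": (150_000, 151_000, "+"),
}

DEFAULT_CLASS_COUNTS = {
    "intergenic": 17,
    "natural_antisense": 4,
    "intronic_antisense": 3,
    "exon_sense_overlapping": 2,
    "intron_sense_overlapping": 2,
    "bidirectional": 2,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the design
    the pipeline emulates (6 vs 6 arrays, fold-change-2 scale effects)."""

    seed: int = 0
    n_per_group: int = 6
    n_lnc_probes: int = 120
    n_mrna_probes: int = 200
    n_de_planted: int = 40
    n_de_down: int | None = None    # planted down-regulated probes; None = half
    planted_log2fc: float = 3.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_coexpr_pairs: int = 20
    coexpr_noise_sd: float = 0.05
    flag_fail_fraction: float = 0.1
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_enhancer_like: int = 5
    chrom: str = "chrS"
    chrom_length: int | None = None    # None = sized automatically
    n_null_sets: int = 6
    pathway_size: int = 20
    n_clinical_per_group: int = 10
    survival_rate_g1: float = 1.0 / 126.0   # events per month
    survival_rate_g2: float = 1.0 / 82.0
    censor_time: float = 150.0              # months
    n_ct_per_group: int = 10
    ct_reference_mean: float = 20.0
    ct_means: dict = field(default_factory=lambda: {"EGF": 26.0, "ABCC6P1": 24.0})
    ct_ddct: dict = field(default_factory=lambda: {"EGF": -2.0, "ABCC6P1": 1.0})
    ct_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (t-test undefined below)")
        counts = [self.n_lnc_probes, self.n_mrna_probes, self.n_de_planted,
                  self.n_coexpr_pairs, self.n_enhancer_like,
                  self.n_clinical_per_group, self.n_ct_per_group]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_de_planted > self.n_mrna_probes:
            raise ValueError("n_de_planted exceeds n_mrna_probes")
        if self.n_de_down is None:
            self.n_de_down = self.n_de_planted // 2
        if not (0 <= self.n_de_down <= self.n_de_planted):
            raise ValueError("n_de_down must lie in [0, n_de_planted]")
        if self.n_coexpr_pairs > min(self.n_lnc_probes, self.n_mrna_probes):
            raise ValueError("n_coexpr_pairs exceeds available probes")
        unknown = set(self.class_counts) - {c.value for c in PositionalClass}
        if unknown:
            raise ValueError(f"unknown positional classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) > self.n_lnc_probes:
            raise ValueError("class_counts exceed n_lnc_probes")
        if self.n_enhancer_like > self.class_counts.get("intergenic", 0):
            raise ValueError("n_enhancer_like exceeds intergenic count")
        if self.survival_rate_g1 <= 0 or self.survival_rate_g2 <= 0:
            raise ValueError("hazards must be positive")
        if not (0 <= self.flag_fail_fraction < 1):
            raise ValueError("flag_fail_fraction must be in [0, 1)")

    # probe / symbol naming -------------------------------------------------
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lnc_probes)]

    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i + 1:04d}" for i in range(self.n_mrna_probes)]

    def mrna_symbols(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_mrna_probes)]


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    de_probe_ids: set = field(default_factory=set)
    de_direction_of: dict = field(default_factory=dict)
    coexpr_pairs: set = field(default_factory=set)      # {(lnc_id, mrna_id)}
    flag_fail_probe_ids: set = field(default_factory=set)
    class_of: dict = field(default_factory=dict)        # lnc_id -> class
    subtype_of: dict = field(default_factory=dict)      # lnc_id -> subtype
    enriched_pathways: set = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "de_probe_ids": sorted(self.de_probe_ids),
            "de_direction_of": dict(sorted(self.de_direction_of.items())),
            "coexpr_pairs": sorted(map(list, self.coexpr_pairs)),
            "flag_fail_probe_ids": sorted(self.flag_fail_probe_ids),
            "class_of": dict(sorted(self.class_of.items())),
            "subtype_of": dict(sorted(self.subtype_of.items())),
            "enriched_pathways": sorted(self.enriched_pathways),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de_probe_ids=set(d["de_probe_ids"]),
            de_direction_of=d["de_direction_of"],
            coexpr_pairs={tuple(p) for p in d["coexpr_pairs"]},
            flag_fail_probe_ids=set(d["flag_fail_probe_ids"]),
            class_of=d["class_of"],
            subtype_of=d["subtype_of"],
            enriched_pathways=set(d["enriched_pathways"]),
        )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    g1 = [f"NP{i + 1}" for i in range(config.n_per_group)]
    g2 = [f"SP{i + 1}" for i in range(config.n_per_group)]
    return g1, g2


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log2 intensity matrix with planted DE probes and co-expressed pairs.

    DE is planted on the first ``n_de_planted`` mRNA probes as a
    ``planted_log2fc`` shift of the group-2 mean. Co-expressed pairs use
    the first ``n_coexpr_pairs`` lncRNA probes: each is an affine copy
    (slope +1 or -1, alternating) of its partner mRNA profile plus
    N(0, coexpr_noise_sd) noise, so partners of DE mRNAs are themselves DE.
    A ``flag_fail_fraction`` of the unplanted probes get detection-call
    probabilities below the retention rule and fail the flag filter by
    design.
    """
    rng = np.random.default_rng([config.seed, 1])
    g1, g2 = sample_ids(config)
    samples = g1 + g2
    n = len(samples)
    probes = config.lnc_ids() + config.mrna_ids()
    n_lnc = config.n_lnc_probes

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, len(probes))
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, (len(probes), n))

    gt = GroundTruth()
    group2_mask = np.array([s in g2 for s in samples])

    # planted DE mRNAs: the first (n_de_planted - n_de_down) go up in
    # group 2, the rest go down, so the planted signal is direction-balanced
    # as on a real array and does not shift whole-column distributions
    de_rows = np.arange(n_lnc, n_lnc + config.n_de_planted)
    n_up = config.n_de_planted - config.n_de_down
    g2_cols = np.where(group2_mask)[0]
    for j, i in enumerate(de_rows):
        sign = 1.0 if j < n_up else -1.0
        values[i, g2_cols] += sign * config.planted_log2fc
        gt.de_probe_ids.add(probes[i])
        up = (sign * config.planted_log2fc) > 0
        gt.de_direction_of[probes[i]] = "up" if up else "down"

    # planted co-expressed lncRNA partners (affine copies of mRNA rows)
    for k in range(config.n_coexpr_pairs):
        lnc_row, mrna_row = k, n_lnc + k
        slope = 1.0 if k % 2 == 0 else -1.0
        values[lnc_row] = (
            baseline[lnc_row]
            + slope * (values[mrna_row] - baseline[mrna_row])
            + rng.normal(0.0, config.coexpr_noise_sd, n)
        )
        gt.coexpr_pairs.add((probes[lnc_row], probes[mrna_row]))
        if probes[mrna_row] in gt.de_probe_ids:
            gt.de_probe_ids.add(probes[lnc_row])
            mdir = gt.de_direction_of[probes[mrna_row]]
            gt.de_direction_of[probes[lnc_row]] = (
                mdir if slope > 0 else ("down" if mdir == "up" else "up")
            )

    # detection flags: planted probes always detectable, a fraction of the
    # rest get Present/Marginal probability below half the samples
    planted = {probes[i] for i in de_rows} | {p for pair in gt.coexpr_pairs for p in pair}
    eligible = [i for i, p in enumerate(probes) if p not in planted]
    n_fail = int(round(config.flag_fail_fraction * len(probes)))
    n_fail = min(n_fail, len(eligible))
    fail_rows = set(rng.choice(eligible, size=n_fail, replace=False).tolist())
    gt.flag_fail_probe_ids = {probes[i] for i in fail_rows}

    flag_values = np.array(["Present", "Marginal", "Absent"])
    good_p = [0.85, 0.10, 0.05]
    fail_p = [0.15, 0.05, 0.80]
    flags = np.empty((len(probes), n), dtype=object)
    for i in range(len(probes)):
        p = fail_p if i in fail_rows else good_p
        flags[i] = rng.choice(flag_values, size=n, p=p)

    groups = pd.Series(
        [GROUP1] * len(g1) + [GROUP2] * len(g2), index=samples, name="group"
    )
    m = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        groups=groups,
        flags=pd.DataFrame(flags, index=probes, columns=samples),
    )
    return m, gt


def probe_annotation(config: SimulationConfig) -> pd.DataFrame:
    """probe_id / probe_type / symbol table for the synthetic array."""
    rows = [
        {"probe_id": p, "probe_type": "lncRNA", "symbol": p}
        for p in config.lnc_ids()
    ] + [
        {"probe_id": p, "probe_type": "mRNA", "symbol": s}
        for p, s in zip(config.mrna_ids(), config.mrna_symbols())
    ]
    return pd.DataFrame(rows, columns=["probe_id", "probe_type", "symbol"])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[GenomicInterval], list[GenomicInterval], GroundTruth]:
    """Gene models, lncRNA loci and enhancer regions realising each class.

    The chromosome is tiled with one 400-kb cassette per lncRNA locus.
    Every cassette carries one 3-exon plus-strand coding gene; the lncRNA
    is placed inside the cassette so that it satisfies exactly the class
    assigned to it (e.g. the bidirectional locus sits head-to-head 501 bp
    from the gene TSS, the intergenic locus 40 kb downstream — adjacent
    within 300 kb but outside the 1-kb bidirectional window). Enhancer
    regions cover the first ``n_enhancer_like`` intergenic loci. Gene k
    carries the symbol of mRNA probe k, so cassette genes of early
    cassettes are the planted DE genes.
    """
    class_list: list[str] = []
    for cls in sorted(config.class_counts):
        class_list.extend([cls] * config.class_counts[cls])
    n_loci = len(class_list)
    n_cassettes = max(n_loci, 1)
    required = n_cassettes * CASSETTE + 10_000
    if config.chrom_length is not None and config.chrom_length < required:
        raise ValueError(
            f"chromosome too short: need {required} bp for {n_cassettes} cassettes"
        )
    if n_loci > config.n_mrna_probes:
        raise ValueError("more loci than mRNA probes to donate gene symbols")

    symbols = config.mrna_symbols()
    genes: list[GeneModel] = []
    for k in range(n_cassettes):
        s = k * CASSETTE + _GENE_OFFSET
        interval = GenomicInterval(config.chrom, s, s + _GENE_LEN, "+", f"G{k + 1}")
        exons = [
            GenomicInterval(config.chrom, s, s + 1_000, "+", f"G{k + 1}"),
            GenomicInterval(config.chrom, s + 4_000, s + 5_000, "+", f"G{k + 1}"),
            GenomicInterval(config.chrom, s + 9_000, s + 10_000, "+", f"G{k + 1}"),
        ]
        genes.append(GeneModel(gene_id=f"G{k + 1}", symbol=symbols[k % len(symbols)],
                               interval=interval, exons=exons))

    lnc_ids = config.lnc_ids()
    loci: list[GenomicInterval] = []
    gt = GroundTruth()
    intergenic_seen = 0
    for k, cls in enumerate(class_list):
        start_off, end_off, strand = _CLASS_LAYOUT[cls]
        base = k * CASSETTE
        lnc = GenomicInterval(
            config.chrom, base + start_off, base + end_off, strand, lnc_ids[k]
        )
        loci.append(lnc)
        gt.class_of[lnc.name] = cls
        if cls == "intergenic":
            intergenic_seen += 1
            gt.subtype_of[lnc.name] = (
                "enhancer_like" if intergenic_seen <= config.n_enhancer_like
                else "lincRNA"
            )
        elif cls in ("natural_antisense", "intronic_antisense"):
            gt.subtype_of[lnc.name] = "antisense"
        else:
            gt.subtype_of[lnc.name] = "other"

    enhancers = [
        GenomicInterval(l.chrom, l.start - 100, l.end + 100, "+", f"ENH_{l.name}")
        for l in loci
        if gt.subtype_of.get(l.name) == "enhancer_like"
    ]
    return genes, loci, enhancers, gt


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write gene/transcript/exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write("\t".join([iv.chrom, "lncforge_sim", "gene",
                                str(iv.start + 1), str(iv.end), ".", iv.strand,
                                ".", attrs]) + "\n")
            tattrs = attrs + f' transcript_id "{g.gene_id}.t1";'
            fh.write("\t".join([iv.chrom, "lncforge_sim", "transcript",
                                str(iv.start + 1), str(iv.end), ".", iv.strand,
                                ".", tattrs]) + "\n")
            for e in g.exons:
                fh.write("\t".join([e.chrom, "lncforge_sim", "exon",
                                    str(e.start + 1), str(e.end), ".", e.strand,
                                    ".", tattrs]) + "\n")


def write_bed6(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end),
                                iv.name, "0", iv.strand]) + "\n")


# ---------------------------------------------------------------------------
# gene sets, clinical, Ct
# ---------------------------------------------------------------------------

def generate_gene_sets(config: SimulationConfig) -> tuple[list[GeneSet], GroundTruth]:
    """KEGG-style sets: one planted on the DE gene symbols, the rest null."""
    rng = np.random.default_rng([config.seed, 3])
    symbols = config.mrna_symbols()
    de_symbols = symbols[: config.n_de_planted]
    gt = GroundTruth()
    sets: list[GeneSet] = []
    planted = de_symbols[: max(1, min(config.pathway_size, len(de_symbols)))]
    sets.append(GeneSet("PATHWAY01", "planted_de_pathway", frozenset(planted)))
    gt.enriched_pathways = {"PATHWAY01"}
    # null sets are random draws from the whole universe so that their
    # overlap with the DE list is exactly chance-level
    size = min(config.pathway_size, max(1, len(symbols)))
    for j in range(config.n_null_sets):
        members = rng.choice(symbols, size=size, replace=False)
        sets.append(
            GeneSet(f"PATHWAY{j + 2:02d}", f"null_pathway_{j + 1}",
                    frozenset(members.tolist()))
        )
    return sets, gt


def generate_clinical(config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival times per group with administrative censoring."""
    rng = np.random.default_rng([config.seed, 4])
    rows = []
    for group, rate, tag in (
        (GROUP1, config.survival_rate_g1, "NPV"),
        (GROUP2, config.survival_rate_g2, "SPV"),
    ):
        t = rng.exponential(1.0 / rate, config.n_clinical_per_group)
        for i, ti in enumerate(t):
            event = 1 if ti <= config.censor_time else 0
            time = min(ti, config.censor_time)
            rows.append({
                "subject_id": f"{tag}{i + 1:02d}",
                "time": max(round(float(time), 2), 0.01),
                "event": event,
                "group": group,
            })
    return pd.DataFrame(rows, columns=["subject_id", "time", "event", "group"])


def generate_ct(config: SimulationConfig) -> pd.DataFrame:
    """qPCR Ct table with a planted ddCt shift in group 2."""
    rng = np.random.default_rng([config.seed, 5])
    rows = []
    for gene in sorted(config.ct_means):
        base = config.ct_means[gene]
        shift = config.ct_ddct.get(gene, 0.0)
        for group, tag, delta in ((GROUP1, "NPQ", 0.0), (GROUP2, "SPQ", shift)):
            for i in range(config.n_ct_per_group):
                rows.append({
                    "sample_id": f"{tag}{i + 1:02d}",
                    "group": group,
                    "target_gene": gene,
                    "ct_target": round(float(
                        rng.normal(base + delta, config.ct_sd)), 4),
                    "ct_reference": round(float(
                        rng.normal(config.ct_reference_mean, config.ct_sd)), 4),
                })
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "target_gene", "ct_target",
                       "ct_reference"],
    )


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def merge_truth(*parts: GroundTruth) -> GroundTruth:
    gt = GroundTruth()
    for p in parts:
        gt.de_probe_ids |= p.de_probe_ids
        gt.de_direction_of.update(p.de_direction_of)
        gt.coexpr_pairs |= p.coexpr_pairs
        gt.flag_fail_probe_ids |= p.flag_fail_probe_ids
        gt.class_of.update(p.class_of)
        gt.subtype_of.update(p.subtype_of)
        gt.enriched_pathways |= p.enriched_pathways
    return gt


def write_bundle(config: SimulationConfig, outdir) -> GroundTruth:
    """Generate and write every pipeline input plus manifest and ground truth.

    Rerunning with the same config produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, gt_expr = generate_expression(config)
    genes, loci, enhancers, gt_ann = generate_annotation(config)
    sets, gt_sets = generate_gene_sets(config)
    clinical = generate_clinical(config)
    ct = generate_ct(config)
    gt = merge_truth(gt_expr, gt_ann, gt_sets)

    m.to_tsv(outdir / "expression.tsv", outdir / "flags.tsv",
             outdir / "samples.tsv")
    probe_annotation(config).to_csv(outdir / "probes.tsv", sep="\t", index=False)
    write_gtf(genes, outdir / "genes.gtf")
    write_bed6(loci, outdir / "lnc_loci.bed")
    write_bed6(enhancers, outdir / "enhancers.bed")
    write_gmt(sets, outdir / "gene_sets.gmt")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    ct.to_csv(outdir / "ct.csv", index=False)
    gt.to_json(outdir / "ground_truth.json")

    manifest = {
        "config": asdict(config),
        "files": sorted(p.name for p in outdir.iterdir()
                        if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return gt
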
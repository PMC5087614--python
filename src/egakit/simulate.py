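"""Synthetic experiment generator with ground truth.

Emulates the structure of FACS-sorted 48-well STRT overexpression libraries
(spike-in rows, GFP+/- sorted wells per construct, heavy zero-inflated tag
counts), a toy genome annotation that places TFEs into known genomic
categories, stage-resolved embryo expression profiles with planted activated
genes, and promoter sequences with planted motif occurrences — so every
downstream stage can be tested against known truth without any download.

Count model: gamma-Poisson (negative binomial).  A per-sample capture
multiplier applies to endogenous and spike-in rows alike, so spike-ins stay
informative about depth; spike-in expectations are otherwise independent of
the construct.  Planted TFEs have their expectation multiplied by 2**lfc in
the GFP-positive wells of their construct only.

One seeded generator per artifact, with a fixed draw order (ladder, baseline
expression, capture efficiencies, planted sets, counts), so every artifact is
bit-reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig, InvalidConfigError
from .containers import SampleSheet, SpikeTagMatrix, SPIKE_PREFIX
from .motif import PWMModel, PromoterWindow, build_pwm
from .tfe import GeneModel, TFERecord
from .utils import child_seed, reverse_complement

EMBRYO_STAGES = ("oocyte", "4cell", "8cell", "morula")


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic experiment."""

    planted_up: dict[str, set[str]] = field(default_factory=dict)
    planted_down: dict[str, set[str]] = field(default_factory=dict)
    planted_lfc: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_activated: dict[str, set[str]] = field(default_factory=dict)
    motif_occurrences: list[tuple[str, int, str]] = field(default_factory=list)
    per_sample_capture: dict[str, float] = field(default_factory=dict)
    spike_concentrations: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for construct in self.planted_up:
            both = self.planted_up[construct] & self.planted_down.get(construct, set())
            if both:
                raise ValueError(f"{construct}: TFEs planted both up and down: {sorted(both)[:3]}")

    def to_json(self, path) -> None:
        def _sets(d):
            return {k: sorted(v) for k, v in d.items()}

        payload = {
            "planted_up": _sets(self.planted_up),
            "planted_down": _sets(self.planted_down),
            "planted_lfc": self.planted_lfc,
            "planted_activated": _sets(self.planted_activated),
            "motif_occurrences": [list(o) for o in self.motif_occurrences],
            "per_sample_capture": self.per_sample_capture,
            "spike_concentrations": self.spike_concentrations,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            planted_up={k: set(v) for k, v in raw["planted_up"].items()},
            planted_down={k: set(v) for k, v in raw["planted_down"].items()},
            planted_lfc=raw["planted_lfc"],
            planted_activated={k: set(v) for k, v in raw["planted_activated"].items()},
            motif_occurrences=[tuple(o) for o in raw["motif_occurrences"]],
            per_sample_capture=raw["per_sample_capture"],
            spike_concentrations=raw["spike_concentrations"],
            params=raw["params"],
        )


def _sample_sheet_rows(config: SimConfig) -> list[dict]:
    rows = []
    for g in config.replicate_design:
        for r in range(1, g.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{g.construct}_{g.gfp_status[:3]}_{r}",
                    "construct": g.construct,
                    "gfp_status": g.gfp_status,
                    "replicate": r,
                    "cells_per_well": g.cells_per_well,
                }
            )
    return rows


def simulate_experiment(
    config: SimConfig,
    tfe_ids: Optional[Sequence[str]] = None,
    planting_pool: Optional[Iterable[str]] = None,
) -> tuple[SpikeTagMatrix, SampleSheet, SyntheticTruth]:
    """Generate one synthetic STRT library with planted differential expression.

    ``tfe_ids`` names the endogenous rows (defaults to TFE000001..); targets
    are planted only among TFEs in ``planting_pool`` (when given) whose
    baseline expression clears ``config.planting_min_expression`` — an effect
    planted on a never-detected TFE is unrecoverable by construction.
    """
    rng = np.random.default_rng(child_seed(config.seed, "experiment"))
    rows = _sample_sheet_rows(config)
    sheet = SampleSheet(pd.DataFrame(rows))
    n_samples = len(rows)

    if tfe_ids is None:
        tfe_ids = [f"TFE{i + 1:06d}" for i in range(config.n_tfes)]
    else:
        tfe_ids = list(tfe_ids)
        if len(tfe_ids) != config.n_tfes:
            raise InvalidConfigError("tfe_ids length must equal n_tfes")
    spike_ids = [f"{SPIKE_PREFIX}{i + 1:03d}" for i in range(config.n_spikes)]

    # 1. spike ladder: fixed log-uniform concentration spread shared by all samples
    ladder = np.exp2(rng.uniform(0.0, 10.0, size=config.n_spikes))
    ladder /= ladder.sum()
    # 2. baseline expression: heavy-tailed log-normal (most TFEs near zero)
    base = rng.lognormal(mean=0.0, sigma=config.base_log_sd, size=config.n_tfes)
    base /= base.sum()
    # 3. per-sample capture efficiency
    if config.capture_efficiency_cv > 0:
        sigma = np.sqrt(np.log1p(config.capture_efficiency_cv**2))
        capture = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_samples)
    else:
        capture = np.ones(n_samples)

    endo_mu0 = base * config.library_size_mean * (1.0 - config.spike_fraction)
    spike_mu0 = ladder * config.library_size_mean * config.spike_fraction

    # 4. planted targets per construct, from the expressed (and pooled) TFEs
    pool_mask = endo_mu0 >= config.planting_min_expression
    if planting_pool is not None:
        allowed = set(planting_pool)
        pool_mask &= np.array([t in allowed for t in tfe_ids])
    pool_idx = np.nonzero(pool_mask)[0]
    n_up = int(round(config.frac_up * config.n_tfes))
    n_down = int(round(config.frac_down * config.n_tfes))
    constructs_present = {g.construct for g in config.replicate_design}
    effect_constructs = [c for c in config.effect_constructs if c in constructs_present]

    truth = SyntheticTruth(params={"config": _config_dict(config)})
    lfc_matrix = np.zeros((config.n_tfes, n_samples))
    sheet_df = sheet.table
    for construct in effect_constructs:
        take = min(n_up + n_down, len(pool_idx))
        chosen = rng.choice(pool_idx, size=take, replace=False)
        up_idx, down_idx = chosen[:min(n_up, take)], chosen[min(n_up, take):]
        lfcs = {}
        pos_cols = sheet_df.index[
            (sheet_df["construct"] == construct) & (sheet_df["gfp_status"] == "positive")
        ].to_numpy()
        for idx_set, sign in ((up_idx, 1.0), (down_idx, -1.0)):
            for i in idx_set:
                mag = max(config.lfc_min, rng.normal(config.lfc_mean, config.lfc_sd))
                lfcs[tfe_ids[i]] = sign * mag
                lfc_matrix[i, pos_cols] = sign * mag
        truth.planted_up[construct] = {tfe_ids[i] for i in up_idx}
        truth.planted_down[construct] = {tfe_ids[i] for i in down_idx}
        truth.planted_lfc[construct] = lfcs

    # 5. gamma-Poisson counts
    mu = np.vstack(
        [
            endo_mu0[:, None] * np.exp2(lfc_matrix) * capture[None, :],
            spike_mu0[:, None] * np.ones((1, n_samples)) * capture[None, :],
        ]
    )
    if config.dispersion > 1e-12:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)

    matrix = SpikeTagMatrix(
        pd.DataFrame(counts, index=tfe_ids + spike_ids,
                     columns=[r["sample_id"] for r in rows])
    )
    truth.per_sample_capture = dict(zip(matrix.samples, capture.astype(float)))
    truth.spike_concentrations = dict(zip(spike_ids, (spike_mu0).astype(float)))
    return matrix, sheet, truth


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["replicate_design"] = [list(asdict(g).values()) for g in config.replicate_design]
    d["effect_constructs"] = list(config.effect_constructs)
    return d


# ---------------------------------------------------------------------------
# genome annotation


@dataclass
class GenomeAnnotation:
    contig_lengths: dict[str, int]
    sequences: dict[str, str]
    genes: list[GeneModel]
    tfes: list[TFERecord]  # categories assigned by construction
    tss_table: pd.DataFrame  # tfe_id, gene_id, chrom, pos, strand, category


#: fractions of TFEs placed per genomic category (most at coding 5'UTRs, a
#: visible minority without previous annotation)
CATEGORY_FRACTIONS = {
    "utr5_coding": 0.60,
    "coding_exon": 0.10,
    "intron": 0.10,
    "noncoding_gene": 0.05,
    "intergenic_novel": 0.15,
}

_MARGIN = 2600  # keeps every -2000/+500 promoter window inside its contig
_GENE_PITCH = 5200


def _coding_gene(gene_id: str, chrom: str, start: int, strand: str) -> GeneModel:
    """A three-exon coding gene occupying [start, start+2000)."""
    e = start + 2000
    if strand == "+":
        exons = [(start, start + 300), (start + 800, start + 1100), (start + 1600, e)]
        cds = (start + 250, start + 1800)
    else:
        exons = [(start, start + 400), (start + 900, start + 1200), (start + 1700, e)]
        cds = (start + 200, e - 250)
    return GeneModel(gene_id, chrom, strand, start, e, exons, cds[0], cds[1])


def simulate_genome_annotation(config: SimConfig, with_sequence: bool = True) -> GenomeAnnotation:
    """Toy genome with gene models and TFEs of known category.

    Every TFE maps to a coding gene's 5'UTR, a coding exon, an intron, a
    non-coding gene or intergenic space *by construction*, with the category
    recorded; genes are placed far enough from contig edges that every
    -2000/+500 promoter window is valid.
    """
    if config.n_tfes < 1:
        raise InvalidConfigError("n_tfes must be >= 1")
    rng = np.random.default_rng(child_seed(config.seed, "annotation"))
    n = config.n_tfes
    counts = {k: int(round(v * n)) for k, v in CATEGORY_FRACTIONS.items()}
    counts["utr5_coding"] += n - sum(counts.values())

    n_coding = max(counts["utr5_coding"], 1)
    n_noncoding = counts["noncoding_gene"]
    n_contigs = 4 if n_coding >= 4 else 1
    genes: list[GeneModel] = []
    tfes: list[TFERecord] = []
    rows = []
    cursors = {f"chr{i + 1}": _MARGIN for i in range(n_contigs)}
    contig_names = list(cursors)

    def _add_tfe(kind: str, chrom: str, peak: int, strand: str, gene_id: Optional[str]):
        k = len(tfes) + 1
        if strand == "+":
            start, end = peak, peak + 60
        else:
            start, end = peak - 59, peak + 1
        rec = TFERecord(f"TFE{k:06d}", chrom, start, end, strand, peak,
                        category=kind, gene_id=gene_id)
        tfes.append(rec)
        rows.append({"tfe_id": rec.id, "gene_id": gene_id or "", "chrom": chrom,
                     "pos": peak, "strand": strand, "category": kind})

    coding_genes = []
    for i in range(n_coding):
        chrom = contig_names[i % n_contigs]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom]
        g = _coding_gene(f"GENE{i + 1:05d}", chrom, start, strand)
        cursors[chrom] = start + _GENE_PITCH
        genes.append(g)
        coding_genes.append(g)
        tss = g.tx_start if strand == "+" else g.tx_end - 1
        _add_tfe("utr5_coding", chrom, tss, strand, g.gene_id)

    for i in range(n_noncoding):
        chrom = contig_names[i % n_contigs]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom]
        g = GeneModel(f"NCG{i + 1:05d}", chrom, strand, start, start + 600,
                      [(start, start + 600)])
        cursors[chrom] = start + _GENE_PITCH
        genes.append(g)
        peak = start + int(rng.integers(60, 540))
        _add_tfe("noncoding_gene", chrom, peak, strand, g.gene_id)

    for _ in range(counts["coding_exon"]):
        g = coding_genes[int(rng.integers(len(coding_genes)))]
        lo, hi = g.exons[1]
        _add_tfe("coding_exon", g.chrom, int(rng.integers(lo, hi)), g.strand, g.gene_id)
    for _ in range(counts["intron"]):
        g = coding_genes[int(rng.integers(len(coding_genes)))]
        lo, hi = g.exons[0][1], g.exons[1][0]
        _add_tfe("intron", g.chrom, int(rng.integers(lo + 1, hi - 1)), g.strand, g.gene_id)
    for _ in range(counts["intergenic_novel"]):
        chrom = contig_names[int(rng.integers(n_contigs))]
        start = cursors[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        peak = start + int(rng.integers(100, 2000))
        cursors[chrom] = start + 2600
        _add_tfe("intergenic_novel", chrom, peak, strand, None)

    contig_lengths = {c: cursors[c] + _MARGIN for c in contig_names}
    sequences = {}
    if with_sequence:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for c, length in contig_lengths.items():
            codes = rng.integers(0, 4, size=length)
            sequences[c] = bases[codes].tobytes().decode("ascii")

    tss_table = pd.DataFrame(rows)
    return GenomeAnnotation(contig_lengths, sequences, genes, tfes, tss_table)


def leutx_fixture_tfe() -> TFERecord:
    """The LEUTX TFE fixture FE270433 (chr19:40269482-40269570, + strand),
    stored verbatim for coordinate/parser tests; the peak is the annotated
    TSS one base into the cluster."""
    return TFERecord("FE270433", "chr19", 40269482, 40269570, "+",
                     peak=40269483, category="utr5_coding", gene_id="LEUTX")


# ---------------------------------------------------------------------------
# motif planting


def plant_motifs(
    promoters: Sequence[PromoterWindow],
    pwm: PWMModel,
    rate_target: float,
    rate_background: float,
    target_ids: Iterable[str],
    seed: int = 0,
) -> tuple[list[PromoterWindow], list[tuple[str, int, str]]]:
    """Insert sampled motif instances into promoter sequences.

    Each target promoter independently receives one instance with probability
    ``rate_target`` (background promoters: ``rate_background``) at a uniform
    offset and strand; a minus-strand occurrence is inserted as the reverse
    complement.  Returns new windows (inputs untouched) and the occurrence
    list (promoter id, offset, strand).
    """
    for name, rate in (("rate_target", rate_target), ("rate_background", rate_background)):
        if not 0.0 <= rate <= 1.0:
            raise InvalidConfigError(f"{name}={rate} outside [0, 1]")
    targets = set(target_ids)
    rng = np.random.default_rng(seed)
    m = pwm.length
    out, occurrences = [], []
    for w in promoters:
        rate = rate_target if w.id in targets else rate_background
        seq = w.sequence
        if rng.random() < rate:
            if len(seq) < m:
                raise InvalidConfigError(f"promoter {w.id} shorter than the motif")
            instance = pwm.sample(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            offset = int(rng.integers(0, len(seq) - m + 1))
            inserted = instance if strand == "+" else reverse_complement(instance)
            seq = seq[:offset] + inserted + seq[offset + m:]
            occurrences.append((w.id, offset, strand))
        out.append(PromoterWindow(w.id, w.chrom, w.start, w.end, w.strand, seq))
    return out, occurrences


_EGA_CONSENSUS = "TGCCAGGATTAGCYRTGGCWGGATTAKCMTGGCGCA"


def synthetic_ega_motif(granularity: float = 1e-3) -> PWMModel:
    """A synthetic 36 bp stand-in for the EGA promoter motif.

    The published 36 bp matrix lives in its study's supplement and is not
    shipped here; this synthetic consensus (two GGATTA paired-class homeodomain
    core sites with degenerate flanks) has comparable length and information
    content and is used by the examples and simulations.
    """
    return build_pwm(_EGA_CONSENSUS, pseudocount=0.02, granularity=granularity,
                     name="ega36_synthetic")


# ---------------------------------------------------------------------------
# embryo stage profiles


def simulate_embryo_profiles(
    config: SimConfig,
    gene_ids: Optional[Sequence[str]] = None,
    planted_targets: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Stage x gene expression table with a planted activated-gene set.

    Activated genes rise at the 4-cell -> 8-cell transition (embryo genome
    activation) by more than ``config.activation_fold`` relative to the oocyte
    and 4-cell baseline, then fall at the morula; all other genes stay flat up
    to bounded noise.  A fraction ``config.activation_overlap`` of the
    activated set is drawn from ``planted_targets`` when given.
    """
    rng = np.random.default_rng(child_seed(config.seed, "embryo"))
    if gene_ids is None:
        gene_ids = [f"GENE{i + 1:05d}" for i in range(max(config.n_activated * 10, 100))]
    gene_ids = list(gene_ids)
    n_act = min(config.n_activated, len(gene_ids))
    targets = sorted(set(planted_targets or ()) & set(gene_ids))
    n_from_targets = min(int(round(config.activation_overlap * n_act)), len(targets))
    activated = set(
        rng.choice(targets, size=n_from_targets, replace=False)
    ) if n_from_targets else set()
    remaining = [g for g in gene_ids if g not in activated and g not in set(targets)]
    extra = n_act - len(activated)
    if extra > 0:
        activated |= set(rng.choice(remaining, size=min(extra, len(remaining)), replace=False))

    base = rng.lognormal(mean=2.0, sigma=1.0, size=len(gene_ids))
    table = pd.DataFrame(index=list(EMBRYO_STAGES), columns=gene_ids, dtype=float)
    flat_noise = rng.uniform(0.85, 1.15, size=(4, len(gene_ids)))
    for i, stage in enumerate(EMBRYO_STAGES):
        table.loc[stage] = base * flat_noise[i]
    act_cols = [g for g in gene_ids if g in activated]
    if act_cols:
        boost = config.activation_fold * (1.0 + rng.uniform(0.2, 2.0, size=len(act_cols)))
        oo = table.loc["oocyte", act_cols].to_numpy()
        table.loc["8cell", act_cols] = oo * boost
        table.loc["morula", act_cols] = oo * boost * rng.uniform(0.3, 0.6, size=len(act_cols))
    table.index.name = "stage"
    return table, activated
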
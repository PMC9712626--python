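"""Synthetic inputs with ground truth for every pipeline stage.

The generator emulates a fractionated motor-neuron differentiation time
course: six differentiation days (DIV 0, 3, 7, 14, 21, 35), nucleus and
cytoplasm fractions, four control clones (four donors) and three mutant
clones (two donors).  Intron PIR profiles follow nine archetypes — three
nuclear-detained dynamics (N1-N3) and six cytoplasmic dynamics (C1-C6) —
with Gaussian noise clipped to [0, 100].  The mutant perturbation is
unidirectional (PIR increases only), applied in the cytoplasm at DIV 14,
largest for C5 and smaller for C1 and C3.

Companion generators produce genomes/intron annotations with controlled GC
and length, per-RBP cross-link tracks with planted regional enrichments on
the fraction-with->=1-event scale, and bimodal log2 expression with planted
miRNA-target shifts in two contrasts.  Everything is driven by one seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clip_enrichment import REGION_NAMES, define_regions
from .types import CrosslinkTrack, DETable, IntronRecord, PIRMatrix, SampleSheet, TargetSet

DEFAULT_DIVS = (0, 3, 7, 14, 21, 35)

GROUPS = ("N1", "N2", "N3", "C1", "C2", "C3", "C4", "C5", "C6")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeSpec:
    """Mean PIR dynamics of one intron group.

    ``nuclear_profile`` / ``cytoplasmic_profile`` map DIV -> mean PIR;
    ``mutant_delta`` maps (div_day, fraction) -> additive PIR shift applied
    to mutant samples (>= 0: the perturbation only increases retention).
    """

    group_label: str
    nuclear_profile: dict
    cytoplasmic_profile: dict
    mutant_delta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prof in (self.nuclear_profile, self.cytoplasmic_profile):
            for v in prof.values():
                if not (0 <= v <= 100):
                    raise ConfigError(f"{self.group_label}: profile mean {v} outside [0,100]")
        for d in self.mutant_delta.values():
            if d < 0:
                raise ConfigError(f"{self.group_label}: mutant deltas must be >= 0")

    def mean(self, div_day: int, fraction: str, genotype: str) -> float:
        prof = self.nuclear_profile if fraction == "nucleus" else self.cytoplasmic_profile
        mu = prof[div_day]
        if genotype == "mutant":
            mu += self.mutant_delta.get((div_day, fraction), 0.0)
        return float(np.clip(mu, 0.0, 100.0))


def default_archetypes(divs=DEFAULT_DIVS) -> dict:
    """The nine retention dynamics, anchored per DIV.

    N1 stable nuclear / low cytoplasm; N2 nuclear decline; N3 transient
    nuclear peak; C1 decline in both; C2 rise in both; C3 terminal
    cytoplasmic rise; C4 constitutively high; C5 early transient peak
    (DIV 7); C6 late transient peak (DIV 21).  Mutant shifts: +15 PIR on C5
    cytoplasm at DIV 14, +5 on C1 and C3.
    """
    anchors = {
        #        nucleus                        cytoplasm
        "N1": ([30, 30, 30, 30, 30, 30], [3, 3, 3, 3, 3, 3]),
        "N2": ([45, 36, 28, 18, 10, 5], [3, 3, 3, 3, 3, 3]),
        "N3": ([12, 25, 45, 20, 12, 10], [3, 3, 3, 3, 3, 3]),
        "C1": ([50, 42, 35, 28, 20, 15], [35, 30, 25, 18, 10, 5]),
        "C2": ([15, 20, 25, 30, 38, 45], [5, 8, 12, 18, 28, 35]),
        "C3": ([25, 25, 25, 25, 25, 25], [7, 7, 7, 7, 12, 30]),
        "C4": ([60, 60, 60, 60, 60, 60], [40, 40, 40, 40, 40, 40]),
        "C5": ([20, 35, 50, 25, 15, 10], [10, 25, 40, 15, 8, 5]),
        "C6": ([10, 12, 15, 25, 45, 18], [5, 6, 8, 15, 35, 12]),
    }
    deltas = {"C5": 15.0, "C1": 5.0, "C3": 5.0}
    out = {}
    for g, (nuc, cyt) in anchors.items():
        md = {}
        if g in deltas:
            md[(14, "cytoplasm")] = deltas[g]
        out[g] = ArchetypeSpec(
            g,
            dict(zip(divs, map(float, nuc))),
            dict(zip(divs, map(float, cyt))),
            md,
        )
    return out


def default_design(divs=DEFAULT_DIVS) -> SampleSheet:
    """Full factorial: DIVs x {nucleus, cytoplasm} x 4 control + 3 mutant clones."""
    clones = [
        ("ctl1", "control", "pt1"),
        ("ctl2", "control", "pt2"),
        ("ctl3", "control", "pt3"),
        ("ctl4", "control", "pt4"),
        ("mut1", "mutant", "pt5"),
        ("mut2", "mutant", "pt5"),
        ("mut3", "mutant", "pt6"),
    ]
    rows = []
    for div in divs:
        for frac in ("nucleus", "cytoplasm"):
            for clone, gt, pt in clones:
                rows.append(
                    {
                        "sample_id": f"{frac[:3]}_d{div}_{clone}",
                        "fraction": frac,
                        "div_day": div,
                        "genotype": gt,
                        "clone_id": clone,
                        "patient_id": pt,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


@dataclass
class SimConfig:
    """All knobs of the generator; one master seed drives everything."""

    seed: int = 0
    n_introns_per_group: int = 200
    noise_sd: float = 5.0
    design: SampleSheet = None
    archetypes: dict = None
    # genome / introns
    introns_per_gene: int = 3
    intron_length: int = 300
    exon_length: int = 60
    gc_target: float = 0.45
    # cross-links
    n_rbps: int = 10
    crosslink_p0: float = 0.2
    enriched_pairs: tuple = ()  # of (rbp, group, region, fold)
    # expression
    n_genes: int = 5200
    expressed_fraction: float = 0.75
    mu_off: float = 1.0
    mu_on: float = 9.0
    expr_sd: float = 1.0
    n_expr_replicates: int = 4
    # miRNA targets
    n_target_sets: int = 2
    targets_per_set: int = 200
    target_log2fc_time: float = -0.5  # control DIV 7 -> 14
    target_log2fc_mutant: float = 0.5  # mutant vs control at DIV 14

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = default_design()
        if self.archetypes is None:
            self.archetypes = default_archetypes(tuple(self.design.div_days))
        if self.n_introns_per_group <= 0 or self.n_rbps <= 0 or self.n_genes <= 0:
            raise ConfigError("counts must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for _, _, _, fold in self.enriched_pairs:
            if fold < 1:
                raise ConfigError("enrichment folds must be >= 1")
        if self.mu_on <= self.mu_off:
            raise ConfigError("mu_on must exceed mu_off")
        fractions = set(self.design.table["fraction"])
        if fractions != {"nucleus", "cytoplasm"}:
            raise ConfigError("design must contain both nucleus and cytoplasm samples")


@dataclass
class SimTruth:
    """Planted ground truth: the labels every recovery test compares against."""

    intron_group: dict = field(default_factory=dict)  # intron_id -> group label
    intron_gene: dict = field(default_factory=dict)  # intron_id -> gene_id
    retained_introns: set = field(default_factory=set)
    planted_folds: dict = field(default_factory=dict)  # (rbp, group, region) -> fold
    gene_expressed: dict = field(default_factory=dict)  # gene_id -> bool
    mirna_targets: dict = field(default_factory=dict)  # set_name -> frozenset of genes
    target_shifts: dict = field(default_factory=dict)  # set_name -> (time, mutant) log2FC


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str hash is salted per run)
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), tag]))


def intron_ids_by_group(config: SimConfig) -> dict:
    return {
        g: [f"{g}_i{k:04d}" for k in range(config.n_introns_per_group)]
        for g in config.archetypes
    }


def simulate_pir(config: SimConfig):
    """PIR = clip(archetype mean + mutant delta + N(0, noise_sd), 0, 100)."""
    rng = _rng(config, "pir")
    design = config.design
    ids = intron_ids_by_group(config)
    intron_ids = [i for g in config.archetypes for i in ids[g]]
    mean_rows = []
    for g, arch in config.archetypes.items():
        mu = [
            arch.mean(int(r.div_day), r.fraction, r.genotype)
            for r in design.table.itertuples()
        ]
        mean_rows.append(np.tile(mu, (config.n_introns_per_group, 1)))
    means = np.vstack(mean_rows)
    noise = rng.normal(0.0, config.noise_sd, size=means.shape) if config.noise_sd > 0 else 0.0
    values = np.clip(means + noise, 0.0, 100.0)
    pir = PIRMatrix(
        pd.DataFrame(values, index=intron_ids, columns=design.sample_ids), design
    )
    truth = SimTruth(intron_group={i: g for g in config.archetypes for i in ids[g]})
    return pir, truth


def _random_seq(rng, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def simulate_genome_and_introns(config: SimConfig, truth: SimTruth | None = None):
    """One contig per gene; ``introns_per_gene`` introns per gene, exons between.

    The first intron of each gene is the "retained" one carrying a group
    label (cycled through the archetypes to match simulate_pir ids); the
    remaining introns of the gene are non-retained background for the
    per-intron enrichment statistic.  Returns (sequences, introns, truth).
    """
    if config.intron_length < 3 * 30 + 1:
        raise ConfigError("intron_length too short for the 5-region layout (>= 91 nt)")
    if config.exon_length < 30:
        raise ConfigError("exon_length must be >= 30 nt")
    rng = _rng(config, "genome")
    truth = truth or SimTruth()
    ids = intron_ids_by_group(config)
    sequences, introns = {}, []
    for g in config.archetypes:
        for retained_id in ids[g]:
            gene_id = f"gene_{retained_id}"
            n_int = config.introns_per_gene
            strand = "+" if rng.random() < 0.5 else "-"
            seq_parts, pos = [], 0
            exon_bounds, intron_bounds = [], []
            for k in range(n_int + 1):
                seq_parts.append(_random_seq(rng, config.exon_length, config.gc_target))
                exon_bounds.append((pos, pos + config.exon_length))
                pos += config.exon_length
                if k < n_int:
                    seq_parts.append(_random_seq(rng, config.intron_length, config.gc_target))
                    intron_bounds.append((pos, pos + config.intron_length))
                    pos += config.intron_length
            chrom = gene_id
            sequences[chrom] = "".join(seq_parts)
            for k, (s, e) in enumerate(intron_bounds):
                iid = retained_id if k == 0 else f"{retained_id}_nr{k}"
                introns.append(
                    IntronRecord(
                        intron_id=iid,
                        gene_id=gene_id,
                        chrom=chrom,
                        start=s,
                        end=e,
                        strand=strand,
                        upstream_exon_start=exon_bounds[k][0],
                        downstream_exon_end=exon_bounds[k + 1][1],
                    )
                )
                truth.intron_gene[iid] = gene_id
                if k == 0:
                    truth.retained_introns.add(iid)
                    truth.intron_group.setdefault(iid, g)
    return sequences, introns, truth


def simulate_crosslinks(config: SimConfig, introns, groups: dict, truth: SimTruth | None = None):
    """Per-(rbp, intron, region) hits at baseline probability p0.

    Planted (rbp, group, region) folds raise the hit probability to
    min(1, fold * p0); a hit places one event uniformly in the region.
    ``groups`` maps intron_id -> group label (background introns absent).
    """
    rng = _rng(config, "clip")
    truth = truth or SimTruth()
    p0 = config.crosslink_p0
    enriched = {}
    for rbp, group, region, fold in config.enriched_pairs:
        if fold * p0 > 1:
            import warnings

            warnings.warn(f"fold*p0 = {fold * p0:.2f} > 1 for {(rbp, group, region)}; capped")
        enriched[(rbp, group, region)] = fold
        truth.planted_folds[(rbp, group, region)] = fold
    rbp_names = [f"RBP{j:03d}" for j in range(config.n_rbps)]
    region_sets = {iv.intron_id: define_regions(iv) for iv in introns}
    tracks = []
    for rbp in rbp_names:
        positions = set()
        for iv in introns:
            rs = region_sets[iv.intron_id]
            g = groups.get(iv.intron_id)
            for region in REGION_NAMES:
                win = rs.regions[region]
                if win is None:
                    continue
                fold = enriched.get((rbp, g, region), 1.0)
                p = min(1.0, fold * p0)
                if rng.random() < p:
                    pos = int(rng.integers(win[0], win[1]))
                    positions.add((iv.chrom, pos, iv.strand))
        tracks.append(CrosslinkTrack(rbp, positions))
    return tracks, truth


def _expression_conditions():
    # the two contrasts the miRNA analysis uses
    return [
        ("control", 7),
        ("control", 14),
        ("mutant", 14),
    ]


def simulate_expression(config: SimConfig, truth: SimTruth | None = None):
    """Bimodal log2 expression plus planted miRNA-target shifts.

    Off genes ~ N(mu_off, sd), on genes ~ N(mu_on, sd), per replicate and
    condition.  Target genes of the first (non-control) target sets get
    ``target_log2fc_time`` added in control DIV 14 vs DIV 7 and
    ``target_log2fc_mutant`` in mutant vs control at DIV 14.  The last
    target set is a negative control with no shift.  DE tables are Welch
    t-tests on the replicate values.  Returns (matrix, de_tables, sets, truth).
    """
    rng = _rng(config, "expr")
    truth = truth or SimTruth()
    genes = [f"G{k:05d}" for k in range(config.n_genes)]
    on = rng.random(config.n_genes) < config.expressed_fraction
    truth.gene_expressed = dict(zip(genes, map(bool, on)))
    expressed_genes = [g for g, flag in zip(genes, on) if flag]

    # target sets are drawn from expressed genes; the last one is a control set
    sets = []
    pool = np.array(expressed_genes)
    for s in range(config.n_target_sets):
        chosen = rng.choice(pool, size=min(config.targets_per_set, len(pool)), replace=False)
        is_control = s == config.n_target_sets - 1
        name = f"miR-ctrl" if is_control else f"miR-sim{s + 1}"
        sets.append(TargetSet(name, frozenset(chosen.tolist()), is_control=is_control))
        truth.mirna_targets[name] = frozenset(chosen.tolist())
        truth.target_shifts[name] = (
            (0.0, 0.0)
            if is_control
            else (config.target_log2fc_time, config.target_log2fc_mutant)
        )

    base = np.where(on, config.mu_on, config.mu_off)
    conditions = _expression_conditions()
    reps = config.n_expr_replicates
    shifted = {}
    for ts in sets:
        t_shift, m_shift = truth.target_shifts[ts.set_name]
        for g in ts.gene_ids:
            dt, dm = shifted.get(g, (0.0, 0.0))
            shifted[g] = (dt + t_shift, dm + m_shift)
    delta_time = np.array([shifted.get(g, (0.0, 0.0))[0] for g in genes])
    delta_mut = np.array([shifted.get(g, (0.0, 0.0))[1] for g in genes])
    cond_mu = {
        ("control", 7): base,
        ("control", 14): base + on * delta_time,
        ("mutant", 14): base + on * (delta_time + delta_mut),
    }
    data, columns = [], []
    for gt, div in conditions:
        for r in range(reps):
            data.append(cond_mu[(gt, div)] + rng.normal(0.0, config.expr_sd, config.n_genes))
            columns.append(f"{gt}_d{div}_r{r + 1}")
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)

    def _welch_de(cols_a, cols_b, label):
        a = matrix[cols_a].to_numpy()
        b = matrix[cols_b].to_numpy()
        if config.expr_sd > 0:
            t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
            p = np.where(np.isnan(p), 1.0, p)
        else:
            p = np.ones(len(genes))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        return DETable(
            pd.DataFrame(
                {"gene_id": genes, "log2fc": b.mean(axis=1) - a.mean(axis=1), "p_value": p}
            ),
            label,
        )

    cols = lambda gt, div: [f"{gt}_d{div}_r{r + 1}" for r in range(reps)]
    de_time = _welch_de(cols("control", 7), cols("control", 14), "ctrl_div14_vs_div7")
    de_mut = _welch_de(cols("control", 14), cols("mutant", 14), "mut_vs_ctrl_div14")
    return matrix, [de_time, de_mut], sets, truth


def default_enriched_pairs(fold: float = 3.0):
    """Planted regional enrichments used by the study-default simulation."""
    return (
        ("RBP000", "C5", "R2", fold),
        ("RBP001", "C5", "R3", fold),
        ("RBP002", "C1", "R4", fold),
    )


def simulate_all(config: SimConfig):
    """Run every generator off one config; returns a dict of artefacts + truth."""
    pir, truth = simulate_pir(config)
    sequences, introns, truth = simulate_genome_and_introns(config, truth)
    tracks, truth = simulate_crosslinks(config, introns, truth.intron_group, truth)
    expr, de_tables, target_sets, truth = simulate_expression(config, truth)
    return {
        "pir": pir,
        "sequences": sequences,
        "introns": introns,
        "tracks": tracks,
        "expression": expr,
        "de_tables": de_tables,
        "target_sets": target_sets,
        "truth": truth,
    }
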
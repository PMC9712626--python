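"""Splice-site-anchored cross-link enrichment.

Five 30-nt windows are defined around each intron's splice sites, in
transcript orientation:

    R1  last 30 nt of the upstream exon
    R2  first 30 nt of the intron (after the 5' splice site)
    R3  30 nt centred on the intron midpoint
    R4  last 30 nt of the intron (before the 3' splice site)
    R5  first 30 nt of the downstream exon

Cross-link hits are counted per (intron, RBP, region) and per whole intron;
group-level enrichment is the ratio of the group's hit fraction to the
background's, with a one-sided Fisher's exact test for significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import IntronRecord

REGION_WIDTH = 30
REGION_NAMES = ("R1", "R2", "R3", "R4", "R5")
SCOPES = REGION_NAMES + ("whole_intron",)
MIN_REGIONAL_INTRON_LENGTH = 3 * REGION_WIDTH + 1  # R2/R3/R4 must not overlap


class ClipError(ValueError):
    pass


@dataclass(frozen=True)
class RegionSet:
    """The five windows for one intron; each is (start, end) genomic, or None if invalid."""

    intron_id: str
    chrom: str
    strand: str
    regions: dict  # name -> (start, end) or None
    valid: dict  # name -> bool


def define_regions(intron: IntronRecord, width: int = REGION_WIDTH) -> RegionSet:
    """Windows in transcript orientation; strand-aware.

    On the minus strand the upstream exon is the one with larger genomic
    coordinates, so R1/R2 anchor at the intron's genomic end and R4/R5 at
    its genomic start.  R3 is centred on floor((start+end)/2) regardless of
    strand.  Regions are flagged invalid (never raised) when the intron is
    too short for three non-overlapping intronic windows or a flanking exon
    is shorter than the window.
    """
    s, e = intron.start, intron.end
    mid = (s + e) // 2
    r3 = (mid - width // 2, mid + (width - width // 2))
    intronic_ok = intron.length >= 3 * width + 1
    if intron.strand == "+":
        left_is_upstream = True
    else:
        left_is_upstream = False
    left_exon_ok = intron.left_exon_length >= width
    right_exon_ok = intron.right_exon_length >= width
    left_exon_win = (s - width, s)
    right_exon_win = (e, e + width)
    intron_left_win = (s, s + width)
    intron_right_win = (e - width, e)
    if left_is_upstream:
        regions = {
            "R1": left_exon_win,
            "R2": intron_left_win,
            "R3": r3,
            "R4": intron_right_win,
            "R5": right_exon_win,
        }
        valid = {
            "R1": left_exon_ok,
            "R2": intronic_ok,
            "R3": intronic_ok,
            "R4": intronic_ok,
            "R5": right_exon_ok,
        }
    else:
        regions = {
            "R1": right_exon_win,
            "R2": intron_right_win,
            "R3": r3,
            "R4": intron_left_win,
            "R5": left_exon_win,
        }
        valid = {
            "R1": right_exon_ok,
            "R2": intronic_ok,
            "R3": intronic_ok,
            "R4": intronic_ok,
            "R5": left_exon_ok,
        }
    regions = {k: (v if valid[k] else None) for k, v in regions.items()}
    return RegionSet(intron.intron_id, intron.chrom, intron.strand, regions, valid)


@dataclass
class HitMatrix:
    """Boolean hits per (intron, rbp, scope) plus whole-intron event counts."""

    intron_ids: list
    rbp_names: list
    hits: np.ndarray  # introns x rbps x len(SCOPES) bool
    whole_intron_counts: np.ndarray  # introns x rbps int
    region_valid: pd.DataFrame  # introns x R1..R5 bool
    skipped_events: int = 0

    def scope_index(self, scope: str) -> int:
        return SCOPES.index(scope)

    def hit_frame(self, rbp: str, scope: str) -> pd.Series:
        j = self.rbp_names.index(rbp)
        return pd.Series(self.hits[:, j, self.scope_index(scope)], index=self.intron_ids)


def build_hit_matrix(tracks, region_sets, introns) -> HitMatrix:
    """>=1 strand-matched cross-link event per (intron, RBP, region) / whole intron.

    Events on chromosomes absent from the intron annotation are skipped with
    a warning and counted in ``skipped_events``.
    """
    introns = list(introns)
    region_sets = {rs.intron_id: rs for rs in region_sets}
    intron_ids = [iv.intron_id for iv in introns]
    rbp_names = [t.rbp_name for t in tracks]
    known_chroms = {iv.chrom for iv in introns}
    hits = np.zeros((len(introns), len(rbp_names), len(SCOPES)), dtype=bool)
    counts = np.zeros((len(introns), len(rbp_names)), dtype=int)
    valid = pd.DataFrame(
        {r: [region_sets[i].valid[r] for i in intron_ids] for r in REGION_NAMES},
        index=intron_ids,
    )
    skipped = 0
    # sorted event positions per (chrom, strand) per track
    for j, track in enumerate(tracks):
        by_key = {}
        for chrom, pos, strand in track.positions:
            if chrom not in known_chroms:
                skipped += 1
                continue
            by_key.setdefault((chrom, strand), []).append(pos)
        by_key = {k: np.sort(np.asarray(v)) for k, v in by_key.items()}
        for i, iv in enumerate(introns):
            pos = by_key.get((iv.chrom, iv.strand))
            if pos is None:
                continue
            rs = region_sets[iv.intron_id]
            for r in REGION_NAMES:
                win = rs.regions[r]
                if win is None:
                    continue
                lo, hi = np.searchsorted(pos, win[0]), np.searchsorted(pos, win[1])
                if hi > lo:
                    hits[i, j, SCOPES.index(r)] = True
            lo, hi = np.searchsorted(pos, iv.start), np.searchsorted(pos, iv.end)
            counts[i, j] = hi - lo
            hits[i, j, SCOPES.index("whole_intron")] = hi > lo
    if skipped:
        warnings.warn(f"{skipped} cross-link events on unknown chromosomes were skipped")
    return HitMatrix(intron_ids, rbp_names, hits, counts, valid, skipped)


@dataclass
class EnrichmentRow:
    group_label: str
    rbp_name: str
    scope: str
    fraction_group: float
    fraction_background: float
    enrichment: float  # NaN when background fraction is 0
    p_value: float
    n_group: int
    n_background: int


def group_enrichment(
    hits: HitMatrix,
    group: set,
    background: set,
    scope: str,
    group_label: str = "group",
    alternative: str = "greater",
) -> list:
    """Enrichment = (group hit fraction) / (background hit fraction), per RBP.

    Fisher's exact p from the 2x2 table [group hit/miss; non-group hit/miss]
    where non-group = background minus group.  Regional scopes only count
    introns whose region is valid.
    """
    if not group <= background:
        raise ClipError("group must be a subset of the background")
    idx = {iid: i for i, iid in enumerate(hits.intron_ids)}
    if scope in REGION_NAMES:
        usable = set(hits.region_valid.index[hits.region_valid[scope]])
    else:
        usable = set(hits.intron_ids)
    g_idx = np.array([idx[i] for i in sorted(group & usable)], dtype=int)
    b_idx = np.array([idx[i] for i in sorted(background & usable)], dtype=int)
    ng_idx = np.array([idx[i] for i in sorted((background - group) & usable)], dtype=int)
    s = hits.scope_index(scope)
    rows = []
    for j, rbp in enumerate(hits.rbp_names):
        gh = int(hits.hits[g_idx, j, s].sum()) if len(g_idx) else 0
        bh = int(hits.hits[b_idx, j, s].sum()) if len(b_idx) else 0
        nh = int(hits.hits[ng_idx, j, s].sum()) if len(ng_idx) else 0
        fg = gh / len(g_idx) if len(g_idx) else np.nan
        fb = bh / len(b_idx) if len(b_idx) else np.nan
        enr = fg / fb if fb and fb > 0 else np.nan
        table = [[gh, len(g_idx) - gh], [nh, len(ng_idx) - nh]]
        p = stats.fisher_exact(table, alternative=alternative)[1] if len(ng_idx) else 1.0
        rows.append(
            EnrichmentRow(group_label, rbp, scope, fg, fb, enr, float(p), len(g_idx), len(b_idx))
        )
    return rows


def enrichment_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group_label,
                "rbp": r.rbp_name,
                "scope": r.scope,
                "fraction_group": r.fraction_group,
                "fraction_background": r.fraction_background,
                "enrichment": r.enrichment,
                "p_value": r.p_value,
                "n_group": r.n_group,
                "n_background": r.n_background,
            }
            for r in rows
        ]
    )


def per_intron_enrichment(tracks, intron: IntronRecord, nonretained_same_gene) -> float:
    """Length-normalised cross-link rate of the intron over its gene's non-retained introns.

    Pools events from every supplied track; undefined (error) when the gene
    has no non-retained introns, NaN when the background rate is 0.
    """
    others = list(nonretained_same_gene)
    if not others:
        raise ClipError(f"gene {intron.gene_id}: no nonretained introns to compare against")

    def _count(iv):
        n = 0
        for t in tracks:
            for chrom, pos, strand in t.positions:
                if chrom == iv.chrom and strand == iv.strand and iv.start <= pos < iv.end:
                    n += 1
        return n

    rate = _count(intron) / intron.length
    pooled_events = sum(_count(iv) for iv in others)
    pooled_length = sum(iv.length for iv in others)
    bg_rate = pooled_events / pooled_length
    return rate / bg_rate if bg_rate > 0 else float("nan")


def significant_rbps(rows, alpha: float = 0.01) -> set:
    """RBPs enriched (ratio > 1) at Fisher p < alpha; depletions excluded."""
    return {
        r.rbp_name
        for r in rows
        if r.p_value < alpha and np.isfinite(r.enrichment) and r.enrichment > 1
    }


def cluster_groups(table: pd.DataFrame, scopes=REGION_NAMES):
    """Ward linkage on Manhattan distances between per-group enrichment profiles.

    ``table``: long-form enrichment frame (group/rbp/scope/enrichment).
    Undefined enrichments are imputed as 1.0 (no enrichment).  Groups are
    sorted by label first so ties break deterministically.  Returns
    (linkage matrix, group labels in input order).
    """
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ClipError("need >= 2 groups to cluster")
    sub = table[table["scope"].isin(list(scopes))]
    wide = sub.pivot_table(index="group", columns=["rbp", "scope"], values="enrichment", sort=True)
    wide = wide.loc[groups].fillna(1.0)
    dist = pdist(wide.to_numpy(), metric="cityblock")
    linkage = hierarchy.linkage(dist, method="ward")
    return linkage, groups
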
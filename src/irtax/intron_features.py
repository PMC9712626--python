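"""Per-intron sequence/annotation features and the nested-model feature ANOVA.

Features: log-length, GC content, median per-base conservation, per-intron
RBP cross-link enrichment and the number of introns in the host gene
(optionally precomputed splice-site maximum-entropy scores as extra
columns).  Each feature's contribution to maximum PIR is tested by
comparing a full ordinary-least-squares model against the reduced model
without that feature (F-test).

A PTC scan translates the intron-retaining transcript from the CDS start
and applies the 50-nt rule: a stop more than 50 nt upstream of the final
exon-exon junction is a premature termination codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

STOP_CODONS = {"TAA", "TAG", "TGA"}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FeatureError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N bases excluded from both numerator and denominator."""
    if not sequence:
        raise FeatureError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise FeatureError("sequence has no unambiguous bases")
    return gc / acgt


def length_transform(length, mode: str = "log10", max_length: float | None = None):
    """Size feature for the ANOVA: log10(length) by default.

    ``mode='logit'`` computes logit(length / max_length) for those who want
    the bounded-ratio variant; lengths are treated as counts, so the log is
    the default.
    """
    length = np.asarray(length, dtype=float)
    if mode == "log10":
        return np.log10(length)
    if mode == "logit":
        if max_length is None:
            max_length = float(length.max()) + 1.0
        p = length / max_length
        return np.log(p / (1 - p))
    raise FeatureError(f"unknown length transform {mode!r}")


def median_conservation(track, interval) -> float:
    """Median per-base score over the covered part of [start, end).

    ``track``: iterable of (chrom, start, end, score) bedGraph-style rows.
    Requires >= 50% base coverage of the interval, else undefined-feature.
    """
    chrom, start, end = interval
    if end <= start:
        raise FeatureError("empty interval")
    per_base = []
    for tchrom, ts, te, score in track:
        if tchrom != chrom:
            continue
        lo, hi = max(ts, start), min(te, end)
        if hi > lo:
            per_base.extend([score] * (hi - lo))
    if not per_base:
        raise FeatureError("no conservation coverage over the interval")
    if len(per_base) < 0.5 * (end - start):
        raise FeatureError(
            f"conservation covers {len(per_base)}/{end - start} bases (< 50%)"
        )
    return float(np.median(per_base))


def ptc_scan(exon_seqs, intron_seq: str, intron_after: int, cds_start: int, nmd_window: int = 50):
    """Scan the intron-retaining transcript for premature termination codons.

    ``exon_seqs``: mature exon sequences 5'->3'; the retained intron is
    inserted after exon index ``intron_after``.  Translation starts at
    transcript coordinate ``cds_start`` (0-based, must point at a base).
    A stop codon is a PTC iff its first base lies more than ``nmd_window``
    nt upstream of the last exon-exon junction of the retaining transcript.
    Returns (has_ptc, ptc_positions, stop_positions).
    """
    if not 0 <= intron_after < len(exon_seqs) - 1:
        raise FeatureError("intron_after must name a junction between two exons")
    parts, junctions, pos = [], [], 0
    for i, ex in enumerate(exon_seqs):
        parts.append(ex)
        pos += len(ex)
        if i == intron_after:
            # retained intron: its boundaries are NOT exon-exon junctions
            parts.append(intron_seq)
            pos += len(intron_seq)
        elif i < len(exon_seqs) - 1:
            junctions.append(pos)
    transcript = "".join(parts).upper()
    if not 0 <= cds_start < len(transcript):
        raise FeatureError("CDS start not found within the transcript")
    # a retained final/only intron leaves no downstream junction: never an NMD target
    last_junction = junctions[-1] if junctions else None
    stops, ptcs = [], []
    for p in range(cds_start, len(transcript) - 2, 3):
        codon = transcript[p : p + 3]
        if codon in STOP_CODONS:
            stops.append(p)
            if last_junction is not None and last_junction - p > nmd_window:
                ptcs.append(p)
            break  # translation terminates at the first stop
    return (len(ptcs) > 0, ptcs, stops)


@dataclass
class AnovaResult:
    feature_name: str
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def pir_feature_anova(features, response, standardize: bool = True) -> list:
    """Full-vs-reduced OLS F-test for each feature's contribution to max PIR.

    ``features``: DataFrame (introns x features, numeric, complete rows
    only); ``response``: max PIR per intron over one compartment's samples.
    F = ((RSS_red - RSS_full)/ddf) / (RSS_full/df_den), p from F(ddf, df_den).
    """
    import pandas as pd

    feats = pd.DataFrame(features).astype(float)
    y = np.asarray(response, dtype=float)
    mask = np.isfinite(y) & np.isfinite(feats.to_numpy()).all(axis=1)
    feats, y = feats.loc[mask], y[mask]
    n, p = feats.shape
    if n < 20:
        raise FeatureError(f"need >= 20 complete rows, got {n}")
    Xf = feats.to_numpy()
    if standardize:
        sd = Xf.std(axis=0)
        if np.any(sd == 0):
            bad = feats.columns[sd == 0].tolist()
            raise CollinearityError(f"constant feature(s): {bad}")
        Xf = (Xf - Xf.mean(axis=0)) / sd
    X_full = np.column_stack([np.ones(n), Xf])
    cond = np.linalg.cond(X_full)
    if cond > 1e8:
        corr = np.corrcoef(Xf, rowvar=False)
        iu = np.triu_indices(p, k=1)
        j = int(np.argmax(np.abs(corr[iu])))
        pair = (feats.columns[iu[0][j]], feats.columns[iu[1][j]])
        raise CollinearityError(f"design matrix condition number {cond:.2g} > 1e8; "
                                f"most correlated pair: {pair}")
    rss_full = _ols_rss(X_full, y)
    df_den = n - (p + 1)
    results = []
    for j, name in enumerate(feats.columns):
        X_red = np.delete(X_full, j + 1, axis=1)
        rss_red = _ols_rss(X_red, y)
        f = ((rss_red - rss_full) / 1.0) / (rss_full / df_den)
        f = max(f, 0.0)
        pval = float(stats.f.sf(f, 1, df_den))
        results.append(AnovaResult(str(name), float(f), max(pval, np.nextafter(0, 1)), 1, df_den))
    return results
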
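"""Threshold rules on PIR matrices: prevalence, NIRT/CIRT classes, dPIR events.

All thresholds use strict inequalities.  Missing PIR values never count as
passing a threshold and are skipped (pairwise) by all means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PIRMatrix, SampleSheet


class ConfigError(ValueError):
    pass


def prevalence_filter(
    pir: PIRMatrix,
    min_pir: float = 10.0,
    min_samples: int = 3,
    compartment: str = "nucleus",
) -> set:
    """Introns with PIR > min_pir in at least min_samples samples of one compartment."""
    sub = pir.subset_samples(fraction=compartment)
    if len(sub.samples) == 0:
        raise ConfigError(f"no samples in compartment {compartment!r}")
    if min_samples > len(sub.samples):
        raise ConfigError(
            f"min_samples={min_samples} exceeds the {len(sub.samples)} "
            f"{compartment} samples available"
        )
    counts = (sub.values > min_pir).sum(axis=1)  # NaN > x is False
    return set(sub.values.index[counts >= min_samples])


@dataclass
class IRCall:
    intron_id: str
    ir_class: str  # NIRT / CIRT / neither
    max_pir_nucleus: float
    max_pir_cytoplasm: float
    condition_of_max: str
    all_missing: bool = False


def classify_nirt_cirt(
    pir: PIRMatrix,
    samples: SampleSheet | None = None,
    summarize: str = "condition_mean",
    nuc_min: float = 20.0,
    cyt_cirt_min: float = 15.0,
    cyt_nirt_max: float = 5.0,
) -> list:
    """NIRT/CIRT calls from compartment maxima of summarised PIR.

    With the default per-condition-mean summary S:
    CIRT iff max S_nucleus > 20 and max S_cytoplasm > 15;
    NIRT iff max S_nucleus > 20 and max S_cytoplasm < 5; else neither.
    ``summarize='any_sample'`` uses per-sample values instead of condition means.
    """
    samples = samples or pir.samples
    if summarize not in ("condition_mean", "any_sample"):
        raise ConfigError(f"unknown summarize mode {summarize!r}")
    calls = []
    for frac in ("nucleus", "cytoplasm"):
        if len(samples.subset(fraction=frac)) == 0:
            raise ConfigError(f"design lacks {frac} samples")
    sub = {f: pir.subset_samples(fraction=f) for f in ("nucleus", "cytoplasm")}
    summary = {}
    for f, m in sub.items():
        if summarize == "condition_mean":
            summary[f] = m.condition_means()
        else:
            summary[f] = m.values
    max_nuc = summary["nucleus"].max(axis=1)
    max_cyt = summary["cytoplasm"].max(axis=1)
    arg_nuc = summary["nucleus"].idxmax(axis=1)
    for iid in pir.intron_ids:
        mn, mc = max_nuc.get(iid, np.nan), max_cyt.get(iid, np.nan)
        all_missing = bool(pd.isna(mn) or pd.isna(mc))
        if all_missing:
            cls = "neither"
        elif mn > nuc_min and mc > cyt_cirt_min:
            cls = "CIRT"
        elif mn > nuc_min and mc < cyt_nirt_max:
            cls = "NIRT"
        else:
            cls = "neither"
        cond = str(arg_nuc.get(iid, "")) if not pd.isna(mn) else ""
        calls.append(IRCall(iid, cls, float(mn), float(mc), cond, all_missing))
    return calls


@dataclass
class DeltaPIREvent:
    intron_id: str
    contrast: tuple
    mean_delta: float
    direction: str  # included / skipped
    n_a: int
    n_b: int


def call_delta_pir(
    pir: PIRMatrix,
    contrast: tuple,
    min_delta: float = 15.0,
    require_expressed: set | None = None,
    intron_to_gene: dict | None = None,
) -> list:
    """Events where |mean PIR(b) - mean PIR(a)| >= min_delta.

    ``contrast`` is a pair of sample-sheet selector dicts, e.g.
    ``({"fraction": "cytoplasm", "div_day": 7, "genotype": "control"}, {...})``.
    When ``require_expressed`` is given, the intron's host gene (via
    ``intron_to_gene``) must be in that set.  direction = "included" when
    retention rises from a to b.
    """
    sel_a, sel_b = contrast
    sub_a = pir.subset_samples(**sel_a)
    sub_b = pir.subset_samples(**sel_b)
    if len(sub_a.samples) == 0 or len(sub_b.samples) == 0:
        raise ConfigError("both contrast conditions need >= 1 sample")
    if require_expressed is not None and intron_to_gene is None:
        raise ConfigError("require_expressed needs an intron_to_gene map")
    mean_a = sub_a.values.mean(axis=1)
    mean_b = sub_b.values.mean(axis=1)
    n_a = sub_a.values.notna().sum(axis=1)
    n_b = sub_b.values.notna().sum(axis=1)
    delta = mean_b - mean_a
    label = (str(sel_a), str(sel_b))
    events = []
    for iid in pir.intron_ids:
        d = delta[iid]
        if pd.isna(d) or abs(d) < min_delta:
            continue
        if require_expressed is not None:
            gene = intron_to_gene.get(iid)
            if gene not in require_expressed:
                continue
        events.append(
            DeltaPIREvent(
                iid,
                label,
                float(d),
                "included" if d > 0 else "skipped",
                int(n_a[iid]),
                int(n_b[iid]),
            )
        )
    return events
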
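"""LC-MS nucleoside quantification arithmetic.

Modified-nucleoside abundance is represented by its ion peak area normalised
to the sum of the four canonical nucleosides (A, C, G, U) within the same
replicate, which cancels injection-amount differences.  Genotype comparisons
report the ratio of mean normalised abundances (mutant over control) with a
delta-method standard error.  The three methylguanosines (m7G, m1G, m2G)
share a mass transition and are disambiguated by retention time in the
elution order m7G < m1G < m2G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QuantError

__all__ = [
    "NucleosideRecord",
    "normalize_abundance",
    "relative_to_control",
    "assign_isomeric_guanosines",
]

CANONICAL_SPECIES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class NucleosideRecord:
    """One integrated LC-MS peak."""

    species: str
    genotype: str
    replicate: int
    retention_time: float  # minutes
    peak_area: float  # arbitrary units, >= 0

    def __post_init__(self) -> None:
        if self.peak_area < 0:
            raise QuantError(f"{self.species}: negative peak area")
        if self.replicate < 1:
            raise QuantError(f"{self.species}: replicate must be >= 1")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "species": [r.species for r in records],
                "genotype": [r.genotype for r in records],
                "replicate": [r.replicate for r in records],
                "peak_area": [r.peak_area for r in records],
            }
        )
    required = {"species", "genotype", "replicate", "peak_area"}
    missing = required - set(df.columns)
    if missing:
        raise QuantError(f"nucleoside table lacks columns: {sorted(missing)}")
    if (df["peak_area"] < 0).any():
        raise QuantError("negative peak areas present")
    return df


def normalize_abundance(records) -> pd.DataFrame:
    """Normalise every species' peak area to the canonical sum of its
    (genotype, replicate) group.

    Accepts a DataFrame (``species, genotype, replicate, peak_area``) or a
    list of :class:`NucleosideRecord`.  Each group must contain all four
    canonical species with a positive total.  Canonical normalised values sum
    to exactly 1 per group, and the result is invariant under any
    per-replicate global scaling of areas.
    """
    df = _as_frame(records)
    out = []
    for (genotype, rep), group in df.groupby(["genotype", "replicate"], sort=False):
        present = set(group["species"])
        lacking = [sp for sp in CANONICAL_SPECIES if sp not in present]
        if lacking:
            raise QuantError(
                f"group ({genotype}, replicate {rep}) lacks canonical species {lacking}"
            )
        canon = group.loc[group["species"].isin(CANONICAL_SPECIES), "peak_area"].sum()
        if canon <= 0:
            raise QuantError(f"group ({genotype}, replicate {rep}) has zero canonical sum")
        sub = group[["species", "genotype", "replicate"]].copy()
        sub["value"] = group["peak_area"] / canon
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def relative_to_control(norm: pd.DataFrame, control_genotype: str) -> pd.DataFrame:
    """Per-species mean ratio to the control genotype with a delta-method SE.

    For each species and genotype the ratio is mean(value) / mean(control
    value); its standard error combines the replicate standard errors of both
    means, ``se_r = r * sqrt((se_m/m)^2 + (se_c/c)^2)``.  The control's own
    ratio is identically 1 with SE 0.
    """
    if control_genotype not in set(norm["genotype"]):
        raise QuantError(f"control genotype {control_genotype!r} absent")
    stats = (
        norm.groupby(["species", "genotype"])["value"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    stats["sem"] = stats["sem"].fillna(0.0)  # single replicate
    ctrl = stats[stats["genotype"] == control_genotype].set_index("species")
    rows = []
    for _, row in stats.iterrows():
        sp = row["species"]
        if sp not in ctrl.index:
            continue
        cm, cs = ctrl.loc[sp, "mean"], ctrl.loc[sp, "sem"]
        if cm == 0:
            raise QuantError(f"control mean is zero for species {sp!r}")
        if row["genotype"] == control_genotype:
            ratio, se = 1.0, 0.0
        else:
            ratio = row["mean"] / cm
            rel_var = 0.0
            if row["mean"] != 0:
                rel_var += (row["sem"] / row["mean"]) ** 2
            rel_var += (cs / cm) ** 2
            se = abs(ratio) * float(np.sqrt(rel_var))
        rows.append(
            {
                "species": sp,
                "genotype": row["genotype"],
                "n_replicates": int(row["count"]),
                "mean_normalized": row["mean"],
                "ratio_to_control": ratio,
                "se_ratio": se,
            }
        )
    return pd.DataFrame(rows)


def assign_isomeric_guanosines(
    peaks: list[tuple[float, float]]
) -> dict[str, tuple[float, float]]:
    """Label three same-transition peaks as m7G, m1G, m2G by retention time.

    ``peaks`` is a list of ``(retention_time, area)``; ascending retention
    time maps to m7G, m1G, m2G.  Exactly three peaks with distinct retention
    times are required.
    """
    if len(peaks) != 3:
        raise QuantError(f"expected exactly 3 isomeric peaks, got {len(peaks)}")
    rts = [rt for rt, _ in peaks]
    if len(set(rts)) != 3:
        raise QuantError("tied retention times cannot be disambiguated")
    ordered = sorted(peaks, key=lambda p: p[0])
    return dict(zip(("m7G", "m1G", "m2G"), ordered))
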
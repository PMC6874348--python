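"""Position-37 modification calling from pileup substitution proportions.

The reverse transcriptase reads unmodified adenosine as A, inosine as G and
N1-methylinosine (m1I) as T, so the base composition of a pileup column at
position 37 identifies the modification state: a T-dominant column over a
reference A implies m1I (both TAD1 and TRM5 active), G-dominant implies
inosine (TAD1 active, TRM5 inactive), A-dominant implies unmodified A (TAD1
inactive).  Genotype contrasts on the T fraction (two-sided Fisher exact
test, Benjamini-Hochberg across genes) quantify m1I depletion.

Proportions are computed directly from pileup counts; deletions are excluded
from the denominator because they reflect RT-stop artefacts rather than
substitution signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import PileupMatrix
from .errors import PileupError
from .reference import TRNAGene, canonical_position

__all__ = [
    "Position37Call",
    "DepletionResult",
    "substitution_profile",
    "call_position37",
    "compare_genotypes",
    "compare_genotypes_batch",
    "classify_rt_base",
    "calls_frame",
]

_STATES = ("unmodified_A", "inosine", "m1I", "mixed", "no_call")

#: Read-out key at a reference A (pathway interpretation per observed base).
RT_BASE_KEY = {
    "T": ("m1I", "TAD1 and TRM5 both active (m1I)"),
    "G": ("inosine", "TAD1 active, TRM5 inactive (I)"),
    "A": ("unmodified_A", "TAD1 inactive (unmodified A)"),
    "C": ("inconsistent", "not explained by the two-step pathway"),
}


@dataclass(frozen=True)
class Position37Call:
    """Substitution proportions and inferred state at position 37 of one gene."""

    gene_id: str
    genotype: str
    coverage: int  # A+C+G+T counts (deletions excluded)
    p_A: float
    p_C: float
    p_G: float
    p_T: float
    p_del: float  # del / (A+C+G+T+del), reported for QC only
    inferred_state: str
    dominant_fraction: float
    counts: tuple[int, int, int, int]  # raw A, C, G, T counts

    @property
    def count_T(self) -> int:
        return self.counts[3]


@dataclass(frozen=True)
class DepletionResult:
    """Genotype contrast of the position-37 T fraction (m1I depletion)."""

    gene_id: str
    delta_pT: float  # reference p_T minus mutant p_T
    p_value: float
    adj_p_value: float | None = None
    significant: bool | None = None


def substitution_profile(
    pileup: PileupMatrix, gene: TRNAGene, window: int = 5
) -> pd.DataFrame:
    """Per-position base proportions around the anticodon.

    Covers positions within ``window`` bases of the anticodon (positions 34-36)
    and of position 37.  Deletions are excluded from the denominator; rows with
    zero coverage are flagged and carry NaN proportions.  The output is
    logo-ready: positions x (p_A, p_C, p_G, p_T).
    """
    if gene.gene_id not in pileup.counts:
        raise PileupError(f"gene {gene.gene_id!r} absent from pileup")
    mat = pileup.counts[gene.gene_id]
    lo = max(0, gene.anticodon_offset - window)
    hi = min(mat.shape[0], gene.pos37_offset + window + 1)
    rows = []
    for pos in range(lo, hi):
        acgt = mat[pos, :4].astype(float)
        cov = int(acgt.sum())
        props = acgt / cov if cov > 0 else np.full(4, np.nan)
        rows.append(
            {
                "position": pos + 1,
                "canonical_label": canonical_position(gene, pos),
                "ref_base": gene.sequence[pos],
                "coverage": cov,
                "p_A": props[0], "p_C": props[1], "p_G": props[2], "p_T": props[3],
                "zero_coverage": cov == 0,
            }
        )
    return pd.DataFrame(rows)


def call_position37(
    pileup: PileupMatrix,
    gene: TRNAGene,
    genotype: str = "",
    min_cov: int = 50,
    dominance: float = 0.8,
) -> Position37Call:
    """Call the modification state at position 37 of one gene.

    With coverage below ``min_cov`` the call is ``no_call``.  Otherwise, at a
    reference A the state is ``m1I`` when the T proportion reaches
    ``dominance``, ``inosine`` when G does, ``unmodified_A`` when A does, and
    ``mixed`` otherwise (the full proportion vector is retained).  At non-A
    reference bases state inference is restricted to dominant-reference
    (``unmodified_ref``) versus ``mixed``; this supports the optional
    m1G read-out mode at G37 sites, which reports p_T without a pathway call.
    """
    if gene.gene_id not in pileup.counts:
        raise PileupError(f"gene {gene.gene_id!r} absent from pileup")
    mat = pileup.counts[gene.gene_id]
    pos = gene.pos37_offset
    a, c, g, t = (int(x) for x in mat[pos, :4])
    d = int(mat[pos, 4])
    cov = a + c + g + t
    if cov > 0:
        p_a, p_c, p_g, p_t = a / cov, c / cov, g / cov, t / cov
    else:
        p_a = p_c = p_g = p_t = float("nan")
    p_del = d / (cov + d) if (cov + d) > 0 else float("nan")
    dominant = max(p_a, p_c, p_g, p_t) if cov > 0 else float("nan")

    if cov < min_cov:
        state = "no_call"
    elif gene.base37 == "A":
        if p_t >= dominance:
            state = "m1I"
        elif p_g >= dominance:
            state = "inosine"
        elif p_a >= dominance:
            state = "unmodified_A"
        else:
            state = "mixed"
    else:
        ref_p = {"A": p_a, "C": p_c, "G": p_g, "T": p_t}[gene.base37]
        state = "unmodified_ref" if ref_p >= dominance else "mixed"
    return Position37Call(
        gene_id=gene.gene_id,
        genotype=genotype,
        coverage=cov,
        p_A=p_a, p_C=p_c, p_G=p_g, p_T=p_t, p_del=p_del,
        inferred_state=state,
        dominant_fraction=dominant,
        counts=(a, c, g, t),
    )


def compare_genotypes(call_ref: Position37Call, call_mut: Position37Call) -> DepletionResult:
    """Contrast the position-37 T fraction between two genotypes.

    The p-value is a two-sided Fisher exact test on the 2x2 table of T versus
    non-T counts (reference genotype versus mutant); ``delta_pT`` is the
    reference-minus-mutant T proportion, positive under m1I depletion in the
    mutant.
    """
    if call_ref.gene_id != call_mut.gene_id:
        raise ValueError(
            f"gene mismatch: {call_ref.gene_id!r} vs {call_mut.gene_id!r}"
        )
    t_ref, t_mut = call_ref.count_T, call_mut.count_T
    table = [[t_ref, call_ref.coverage - t_ref], [t_mut, call_mut.coverage - t_mut]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return DepletionResult(
        gene_id=call_ref.gene_id,
        delta_pT=call_ref.p_T - call_mut.p_T,
        p_value=float(p),
    )


def compare_genotypes_batch(
    pairs: list[tuple[Position37Call, Position37Call]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene contrasts with Benjamini-Hochberg adjustment across genes."""
    results = [compare_genotypes(r, m) for r, m in pairs]
    raw = [r.p_value for r in results]
    if raw:
        reject, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    else:
        reject, adj = np.array([], dtype=bool), np.array([])
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "delta_pT": [r.delta_pT for r in results],
            "p_value": raw,
            "adj_p_value": adj,
            "significant": reject,
        }
    )


def classify_rt_base(observed_base: str, ref_base: str = "A") -> str:
    """Interpret a single called cDNA base at position 37 over a reference A.

    T implies m1I (both enzymes active), G inosine (TRM5 inactive), A
    unmodified (TAD1 inactive); C is inconsistent with the pathway.  Intended
    for Sanger-style single-base read-outs; the base must already be called.
    """
    if ref_base != "A":
        raise ValueError("the two-step pathway key applies to reference A sites")
    base = observed_base.upper()
    if base not in RT_BASE_KEY:
        raise ValueError(f"invalid base symbol {observed_base!r}")
    return RT_BASE_KEY[base][0]


def calls_frame(calls: list[Position37Call]) -> pd.DataFrame:
    """Export calls as the standard table."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "genotype": [c.genotype for c in calls],
            "coverage": [c.coverage for c in calls],
            "p_A": [c.p_A for c in calls],
            "p_C": [c.p_C for c in calls],
            "p_G": [c.p_G for c in calls],
            "p_T": [c.p_T for c in calls],
            "inferred_state": [c.inferred_state for c in calls],
        }
    )
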
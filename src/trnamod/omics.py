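"""Transcriptome/proteome integration, codon-usage bias and qPCR arithmetic.

Differential-abundance filters follow the conventions of the upstream
reports: proteins are called up/down on a *linear* fold change with strict
thresholds (> 1.20 up, < 0.83 down) and an adjusted p-value below alpha;
transcripts on a log2 fold change with an inclusive 2-fold threshold
(|log2FC| >= 1).  Benjamini-Hochberg adjustment is computed over the table's
raw p-values when no adjusted column is supplied.  The central overlap class
is "protein down, mRNA stable": protein-down genes not present in the
transcript-down set, with genes absent from the transcript table treated as
transcript-unchanged (proteomics covers fewer genes than RNA-seq).

Codon-usage bias asks whether a gene set is enriched for codons decoded by
m1I/m1G-modified tRNAs: per-codon two-proportion chi-square tests with BH
correction, plus an aggregate chi-square on pooled modified-versus-other
codon counts.  ``derive_modified_codon_set`` builds the codon set from tRNA
references via Watson-Crick pairing plus wobble rules (G34 reads codon-3' C/U,
U34 reads A/G, inosine-34 reads U/C/A).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import TableError
from .reference import TRNAGene

__all__ = [
    "OverlapClassCounts",
    "filter_differential_proteins",
    "filter_differential_transcripts",
    "overlap_classes",
    "codon_usage_bias",
    "derive_modified_codon_set",
    "qpcr_relative_expression",
    "CodonBiasResult",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _ensure_adjusted(table: pd.DataFrame) -> pd.Series:
    if "adj_p_value" in table.columns and table["adj_p_value"].notna().all():
        return table["adj_p_value"]
    _, adj, _, _ = multipletests(table["p_value"].to_numpy(), method="fdr_bh")
    return pd.Series(adj, index=table.index)


def filter_differential_proteins(
    table: pd.DataFrame,
    up_threshold: float = 1.20,
    down_threshold: float = 0.83,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Label proteins up/down/unchanged on linear fold change + significance.

    ``up`` requires fold change strictly above ``up_threshold`` and
    significance; ``down`` strictly below ``down_threshold``.  Fold changes
    exactly at a threshold are unchanged.  Idempotent: re-filtering a
    filtered table reproduces the labels.
    """
    required = {"gene_id", "fold_change", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise TableError(f"protein table lacks columns: {sorted(missing)}")
    if (table["fold_change"] <= 0).any():
        raise TableError("non-positive protein fold change")
    out = table.copy()
    pcol = _ensure_adjusted(out) if use_adjusted else out["p_value"]
    out["adj_p_value"] = _ensure_adjusted(out)
    sig = pcol < alpha
    out["label"] = "unchanged"
    out.loc[sig & (out["fold_change"] > up_threshold), "label"] = "up"
    out.loc[sig & (out["fold_change"] < down_threshold), "label"] = "down"
    return out


def filter_differential_transcripts(
    table: pd.DataFrame,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Label transcripts up/down/unchanged on |log2FC| >= log2(min_fold)
    (inclusive, "at least") plus significance."""
    required = {"gene_id", "log2fc", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise TableError(f"transcript table lacks columns: {sorted(missing)}")
    out = table.copy()
    pcol = _ensure_adjusted(out) if use_adjusted else out["p_value"]
    out["adj_p_value"] = _ensure_adjusted(out)
    thr = np.log2(min_fold)
    sig = pcol < alpha
    out["label"] = "unchanged"
    out.loc[sig & (out["log2fc"] >= thr), "label"] = "up"
    out.loc[sig & (out["log2fc"] <= -thr), "label"] = "down"
    return out


@dataclass(frozen=True)
class OverlapClassCounts:
    """Counts of the transcript x protein intersection cells.

    ``cells`` maps ``(transcript_label, protein_label)`` to a count over the
    union of gene identifiers (genes missing from a layer are unchanged in
    it); the named fields are the marginals and headline classes.
    """

    protein_up: int
    protein_down: int
    transcript_up: int
    transcript_down: int
    protein_down_mrna_stable: int
    both_down: int
    n_genes: int
    cells: dict[tuple[str, str], int]


def overlap_classes(
    transcripts: pd.DataFrame, proteins: pd.DataFrame
) -> OverlapClassCounts:
    """Cross-classify genes by transcript and protein differential labels.

    Inputs are the classed tables from the two filters (must carry ``label``).
    ``protein_down_mrna_stable`` counts protein-down genes not labelled
    transcript-down ("no detectable reduction in mRNA abundance" is
    operationalised as absence from the transcript-down set).
    """
    for name, tab in (("transcript", transcripts), ("protein", proteins)):
        if "label" not in tab.columns:
            raise TableError(f"{name} table is not classed (no 'label' column)")
        if tab["gene_id"].duplicated().any():
            dups = tab.loc[tab["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise TableError(f"duplicated gene_id in {name} table: {dups!r}")
    t_label = dict(zip(transcripts["gene_id"], transcripts["label"]))
    p_label = dict(zip(proteins["gene_id"], proteins["label"]))
    universe = set(t_label) | set(p_label)
    cells: dict[tuple[str, str], int] = {}
    for gid in universe:
        key = (t_label.get(gid, "unchanged"), p_label.get(gid, "unchanged"))
        cells[key] = cells.get(key, 0) + 1

    def count(tl=None, pl=None) -> int:
        return sum(
            v for (t, p), v in cells.items()
            if (tl is None or t == tl) and (pl is None or p == pl)
        )

    return OverlapClassCounts(
        protein_up=count(pl="up"),
        protein_down=count(pl="down"),
        transcript_up=count(tl="up"),
        transcript_down=count(tl="down"),
        protein_down_mrna_stable=count(pl="down") - count(tl="down", pl="down"),
        both_down=count(tl="down", pl="down"),
        n_genes=len(universe),
        cells=cells,
    )


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass
class CodonBiasResult:
    per_codon: pd.DataFrame
    aggregate_chi2: float
    aggregate_p: float
    no_bias: bool
    modified_freq_set: float
    modified_freq_background: float


def _codon_counts(cds) -> dict[str, int]:
    """Count sense codons in CDS sequences (FASTA text, dict or records)."""
    if isinstance(cds, str):
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(StringIO(cds), "fasta")}
    elif isinstance(cds, dict):
        seqs = {k: str(v) for k, v in cds.items()}
    else:
        seqs = {r.id: str(r.seq) for r in cds}
    counts: dict[str, int] = {}
    for name, seq in seqs.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise TableError(f"CDS {name!r}: length {len(seq)} not divisible by 3")
        if set(seq) - set("ACGT"):
            raise TableError(f"CDS {name!r}: invalid characters")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon not in STOP_CODONS:
                counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_usage_bias(
    gene_set_cds,
    background_cds,
    modified_codons: set[str],
    alpha: float = 0.05,
) -> CodonBiasResult:
    """Test a gene set for enrichment of codons read by modified tRNAs.

    Per-codon relative frequencies (stop codons excluded) are compared
    between the gene set and the background with two-proportion chi-square
    tests, BH-corrected.  The aggregate test pools codon counts into modified
    versus other and applies a chi-square without continuity correction;
    ``no_bias`` is true when the aggregate p exceeds ``alpha``.
    """
    set_counts = _codon_counts(gene_set_cds)
    bg_counts = _codon_counts(background_cds)
    n_set = sum(set_counts.values())
    n_bg = sum(bg_counts.values())
    if n_set == 0 or n_bg == 0:
        raise TableError("empty codon counts")
    codons = sorted(set(set_counts) | set(bg_counts))
    rows = []
    for codon in codons:
        a, b = set_counts.get(codon, 0), bg_counts.get(codon, 0)
        if (a + b) in (0, n_set + n_bg):
            p = 1.0
            chi2 = 0.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(
                [[a, n_set - a], [b, n_bg - b]], correction=False
            )
        rows.append(
            {
                "codon": codon,
                "count_set": a,
                "freq_set": a / n_set,
                "count_background": b,
                "freq_background": b / n_bg,
                "chi2": chi2,
                "p_value": p,
                "modified": codon in modified_codons,
            }
        )
    per_codon = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(per_codon["p_value"].to_numpy(), method="fdr_bh")
    per_codon["adj_p_value"] = adj

    mod_set = sum(c for cod, c in set_counts.items() if cod in modified_codons)
    mod_bg = sum(c for cod, c in bg_counts.items() if cod in modified_codons)
    table = [[mod_set, n_set - mod_set], [mod_bg, n_bg - mod_bg]]
    if mod_set + mod_bg == 0 or (n_set - mod_set) + (n_bg - mod_bg) == 0:
        agg_chi2, agg_p = 0.0, 1.0
    else:
        agg_chi2, agg_p, _, _ = stats.chi2_contingency(table, correction=False)
    return CodonBiasResult(
        per_codon=per_codon,
        aggregate_chi2=float(agg_chi2),
        aggregate_p=float(agg_p),
        no_bias=bool(agg_p > alpha),
        modified_freq_set=mod_set / n_set,
        modified_freq_background=mod_bg / n_bg,
    )


#: Codon third-position bases decoded by each wobble (position 34) base.
_WOBBLE_READS = {
    "G": ("T", "C"),
    "T": ("A", "G"),
    "C": ("G",),
    "A": ("T",),
    "I": ("T", "C", "A"),
}


def derive_modified_codon_set(
    genes: list[TRNAGene],
    treat_a34_as_inosine: bool = True,
) -> set[str]:
    """Codons decoded by tRNAs carrying m1G37 or m1I37.

    A tRNA contributes when its position-37 reference base is G
    (m1G-eligible) or A (m1I-eligible through the TAD1/TRM5 pathway).  Its
    codons are the Watson-Crick reverse complement of the anticodon expanded
    at the third codon position by the wobble rules; with
    ``treat_a34_as_inosine`` an A at position 34 is read as inosine
    (decoding codon-3' U, C and A), the prevalent state of A34 tRNAs.
    """
    codons: set[str] = set()
    for g in genes:
        if g.base37 not in ("A", "G"):
            continue
        anticodon = g.anticodon
        if set(anticodon) - set("ACGT"):
            raise TableError(f"{g.gene_id}: invalid anticodon {anticodon!r}")
        first_two = str(Seq(anticodon[1:]).reverse_complement())
        wobble = anticodon[0]
        if wobble == "A" and treat_a34_as_inosine:
            wobble = "I"
        for third in _WOBBLE_READS[wobble]:
            codon = first_two + third
            if codon not in STOP_CODONS:
                codons.add(codon)
    return codons


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def qpcr_relative_expression(
    cq_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCq method.

    ``cq_table`` has columns ``sample, gene, cq`` (technical replicates are
    averaged).  For each target gene and sample,
    ``rel = 2^-((Cq_target,sample - Cq_ref,sample) -
    (Cq_target,calibrator - Cq_ref,calibrator))``.
    """
    required = {"sample", "gene", "cq"}
    missing = required - set(cq_table.columns)
    if missing:
        raise TableError(f"Cq table lacks columns: {sorted(missing)}")
    mean_cq = cq_table.groupby(["sample", "gene"])["cq"].mean()

    def cq(sample: str, gene: str) -> float:
        try:
            return float(mean_cq.loc[(sample, gene)])
        except KeyError:
            raise TableError(f"missing Cq for sample {sample!r}, gene {gene!r}") from None

    samples = sorted(cq_table["sample"].unique())
    genes = [g for g in cq_table["gene"].unique() if g != reference_gene]
    if calibrator_sample not in samples:
        raise TableError(f"calibrator sample {calibrator_sample!r} absent")
    rows = []
    for gene in genes:
        calib_delta = cq(calibrator_sample, gene) - cq(calibrator_sample, reference_gene)
        for sample in samples:
            delta = cq(sample, gene) - cq(sample, reference_gene)
            ddcq = delta - calib_delta
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "delta_cq": delta,
                    "delta_delta_cq": ddcq,
                    "relative_expression": 2.0 ** (-ddcq),
                }
            )
    return pd.DataFrame(rows)
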
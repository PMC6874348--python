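"""Ground-truthed synthetic inputs for every downstream stage.

Three generators live here:

* :func:`simulate_reads` — tRNA-seq reads under the two-step position-37
  modification model (TAD1 deaminates A37 to inosine, TRM5 then methylates
  inosine to m1I) with the reverse-transcriptase read-out rules: unmodified A
  is read as A, inosine as G, m1I as T, and m1G as G (no misincorporation by
  default, with an optional misread-to-T rate).
* :func:`simulate_nucleoside_table` — replicate LC-MS peak-area tables whose
  noise-free canonical-sum-normalised abundances equal configured truths.
* :func:`simulate_expression_tables` — paired transcript/protein tables with
  a configured overlap structure (notably the protein-down / mRNA-stable
  class) guaranteed to survive the downstream filters.

All generators are seed-reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import QuantError, TableError
from .reference import TRNAGene, parse_trna_fasta

__all__ = [
    "ModState",
    "GenotypeModel",
    "RTSignatureModel",
    "SimulatedReads",
    "simulate_reads",
    "standard_genotype_models",
    "simulate_nucleoside_table",
    "simulate_expression_tables",
    "demo_reference_fasta",
    "demo_reference_genes",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class ModState(str, Enum):
    """Modification state of the base at a modifiable site."""

    A_UNMOD = "A_unmod"
    INOSINE = "inosine"
    M1I = "m1I"
    G_UNMOD = "G_unmod"
    M1G = "m1G"
    C_UNMOD = "C_unmod"


#: Reference bases compatible with each state (inosine/m1I arise from A,
#: m1G from G).
_ALLOWED_REF = {
    ModState.A_UNMOD: "A",
    ModState.INOSINE: "A",
    ModState.M1I: "A",
    ModState.G_UNMOD: "G",
    ModState.M1G: "G",
    ModState.C_UNMOD: "C",
}


@dataclass(frozen=True)
class GenotypeModel:
    """Ground-truth per-site modification-state fractions for one genotype.

    ``sites`` maps ``(gene_id, 0-based offset)`` to a discrete distribution
    over :class:`ModState` (fractions summing to 1).
    """

    genotype_name: str
    sites: dict[tuple[str, int], dict[ModState, float]]

    def __post_init__(self) -> None:
        for key, dist in self.sites.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9 or any(not (0.0 <= f <= 1.0) for f in dist.values()):
                raise ValueError(f"{self.genotype_name} site {key}: fractions must be in [0,1] and sum to 1")


@dataclass(frozen=True)
class RTSignatureModel:
    """Reverse-transcription read-out rules: state -> observed-base distribution.

    ``error_rate`` is the per-base sequencing error (uniform over the other
    three bases).  ``rt_stop`` optionally gives a per-state probability that
    reverse transcription aborts at the modified site, truncating the cDNA so
    the read covers only the 3' side of the site.
    """

    read_out: dict[ModState, dict[str, float]]
    error_rate: float = 0.0
    rt_stop: dict[ModState, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.25):
            raise ValueError("error_rate must be in [0, 0.25]")
        for state, dist in self.read_out.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"read-out distribution for {state} does not sum to 1")

    @classmethod
    def default(cls, error_rate: float = 0.0, m1g_misread_t: float = 0.0,
                rt_stop: dict[ModState, float] | None = None) -> "RTSignatureModel":
        """The standard signature key: A->A, I->G, m1I->T, m1G->G.

        ``m1g_misread_t`` exposes an optional m1G-to-T misread rate; it
        defaults to 0 because that signal is not expected in this read-out.
        """
        return cls(
            read_out={
                ModState.A_UNMOD: {"A": 1.0},
                ModState.INOSINE: {"G": 1.0},
                ModState.M1I: {"T": 1.0},
                ModState.G_UNMOD: {"G": 1.0},
                ModState.M1G: {"G": 1.0 - m1g_misread_t, "T": m1g_misread_t},
                ModState.C_UNMOD: {"C": 1.0},
            },
            error_rate=error_rate,
            rt_stop=rt_stop or {},
        )


def standard_genotype_models(
    genes: list[TRNAGene],
    m1i_fraction: float = 1.0,
) -> dict[str, GenotypeModel]:
    """Genotype models for wild type, *tad1* and *trm5* at position 37.

    At A37 sites the wild type carries m1I (fraction ``m1i_fraction``, the
    remainder unmodified A), *tad1* is unmodified (no deamination) and *trm5*
    stalls at inosine (deaminated but unmethylated).  G37 sites carry m1G in
    wild type and *tad1* but are unmodified in *trm5*; both read as G.
    """
    if not (0.0 <= m1i_fraction <= 1.0):
        raise ValueError("m1i_fraction must be in [0, 1]")

    def _sites(rule) -> dict[tuple[str, int], dict[ModState, float]]:
        out = {}
        for g in genes:
            dist = rule(g.base37)
            if dist is not None:
                out[(g.gene_id, g.pos37_offset)] = dist
        return out

    f = m1i_fraction
    wt_a = {ModState.M1I: f, ModState.A_UNMOD: 1.0 - f} if f < 1.0 else {ModState.M1I: 1.0}
    return {
        "wild_type": GenotypeModel("wild_type", _sites(
            lambda b: wt_a if b == "A" else ({ModState.M1G: 1.0} if b == "G" else None))),
        "tad1": GenotypeModel("tad1", _sites(
            lambda b: {ModState.A_UNMOD: 1.0} if b == "A" else ({ModState.M1G: 1.0} if b == "G" else None))),
        "trm5": GenotypeModel("trm5", _sites(
            lambda b: {ModState.INOSINE: 1.0} if b == "A" else ({ModState.G_UNMOD: 1.0} if b == "G" else None))),
    }


@dataclass
class SimulatedReads:
    """Simulated tRNA-seq reads plus their ground-truth manifest.

    ``reads`` is a list of ``(read_id, sequence)``; ``truth`` has one row per
    (read, modelled site) with the drawn state and the base observed in the
    final read (1-based site coordinate).
    """

    reads: list[tuple[str, str]]
    truth: pd.DataFrame

    def fastq_text(self) -> str:
        """Phred-33 FASTQ with constant quality 'I' (Q40); qualities carry no
        information in this simulation."""
        chunks = []
        for read_id, seq in self.reads:
            chunks.append(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        return "".join(chunks)


def simulate_reads(
    genes: list[TRNAGene],
    genotype: GenotypeModel,
    rt: RTSignatureModel,
    n_reads_per_gene: int,
    seed: int,
) -> SimulatedReads:
    """Draw reads gene by gene under the genotype and RT signature models.

    Each read starts as the gene's mature sequence; at every modelled site a
    base is drawn from the state's read-out distribution, then uniform
    sequencing error at rate ``error_rate`` is applied to every base.  With a
    non-zero RT-stop probability the read is truncated to the 3' side of the
    stopped site.  A fixed seed gives byte-identical output.
    """
    if n_reads_per_gene < 1:
        raise ValueError("n_reads_per_gene must be >= 1")
    gene_by_id = {g.gene_id: g for g in genes}
    for (gene_id, site), dist in genotype.sites.items():
        if gene_id in gene_by_id:
            g = gene_by_id[gene_id]
            if not (0 <= site < len(g.sequence)):
                raise ValueError(f"modelled site {site} outside {gene_id}")
            for state in dist:
                if _ALLOWED_REF[state] != g.sequence[site]:
                    raise ValueError(
                        f"{gene_id} site {site}: state {state.value} incompatible "
                        f"with reference base {g.sequence[site]}"
                    )

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple[str, str, int, str, str]] = []

    for g in genes:
        n = n_reads_per_gene
        L = len(g.sequence)
        mat = np.tile(np.frombuffer(g.sequence.encode(), dtype=np.uint8), (n, 1))
        sites = [(s, d) for (gid, s), d in genotype.sites.items() if gid == g.gene_id]
        site_states: dict[int, np.ndarray] = {}
        read_start = np.zeros(n, dtype=np.int64)

        for site, dist in sorted(sites):
            states = list(dist)
            drawn = rng.choice(len(states), size=n, p=[dist[s] for s in states])
            site_states[site] = np.array([states[i].value for i in range(len(states))], dtype=object)[drawn]
            # read-out base per read
            out = np.empty(n, dtype=np.uint8)
            for i, state in enumerate(states):
                mask = drawn == i
                if not mask.any():
                    continue
                bases = list(rt.read_out[state])
                probs = [rt.read_out[state][b] for b in bases]
                picked = rng.choice(len(bases), size=int(mask.sum()), p=probs)
                codes = np.frombuffer("".join(bases).encode(), dtype=np.uint8)
                out[mask] = codes[picked]
                stop_p = rt.rt_stop.get(state, 0.0)
                if stop_p > 0:
                    stopped = np.zeros(n, dtype=bool)
                    stopped[mask] = rng.random(int(mask.sum())) < stop_p
                    read_start = np.maximum(read_start, np.where(stopped, site + 1, 0))
            mat[:, site] = out

        if rt.error_rate > 0:
            err = rng.random((n, L)) < rt.error_rate
            shift = rng.integers(1, 4, size=(n, L))
            idx = np.searchsorted(_BASES, mat)  # ACGT are sorted ASCII
            mat = np.where(err, _BASES[(idx + shift) % 4], mat)

        raw = mat.tobytes().decode()
        for i in range(n):
            read_id = f"{g.gene_id}|{genotype.genotype_name}|r{i:06d}"
            start = int(read_start[i])
            reads.append((read_id, raw[i * L + start : (i + 1) * L]))
            for site in sorted(site_states):
                truth_rows.append(
                    (read_id, g.gene_id, site + 1, str(site_states[site][i]), chr(mat[i, site]))
                )

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "gene_id", "site", "true_state", "observed_base"]
    )
    return SimulatedReads(reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# LC-MS nucleoside tables
# ---------------------------------------------------------------------------

_CANONICAL = ("A", "C", "G", "U")

#: Retention times (minutes) honouring the isomeric methylguanosine elution
#: order m7G < m1G < m2G; other values are arbitrary but distinct.
_DEFAULT_RT = {
    "A": 4.2, "C": 1.0, "G": 2.5, "U": 1.4,
    "m7G": 2.1, "m1G": 3.4, "m2G": 5.0, "m1I": 3.0,
}

#: Control-genotype normalised abundances for modified species (fraction of
#: the canonical sum); sub-percent levels typical of bulk tRNA digests.
DEFAULT_CONTROL_LEVELS = {"m1G": 0.010, "m1I": 0.0020, "m7G": 0.0060, "m2G": 0.0040}


def simulate_nucleoside_table(
    true_relative_levels: dict[str, float],
    control_levels: dict[str, float] | None = None,
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
    control_genotype: str = "wild_type",
    mutant_genotype: str = "trm5",
) -> pd.DataFrame:
    """Replicate peak-area table with configured true mutant/control ratios.

    The noise-free canonical-sum-normalised abundance of each modified
    species equals ``control_levels[sp]`` in the control genotype and
    ``control_levels[sp] * true_relative_levels[sp]`` in the mutant.
    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (unit mean) is applied to every peak area independently.
    """
    control_levels = dict(DEFAULT_CONTROL_LEVELS if control_levels is None else control_levels)
    for sp, ratio in true_relative_levels.items():
        if sp not in control_levels:
            raise QuantError(f"no control level configured for species {sp!r}")
        if ratio < 0 or control_levels[sp] < 0:
            raise QuantError(f"negative level for species {sp!r}")

    rng = np.random.default_rng(seed)
    canonical_total = 1.0e6  # arbitrary instrument units
    canonical_area = {sp: canonical_total / 4 for sp in _CANONICAL}
    sigma = float(np.sqrt(np.log1p(noise_cv**2))) if noise_cv > 0 else 0.0

    rows = []
    for genotype in (control_genotype, mutant_genotype):
        for rep in range(1, replicates + 1):
            areas = dict(canonical_area)
            for sp, level in control_levels.items():
                ratio = true_relative_levels.get(sp, 1.0) if genotype == mutant_genotype else 1.0
                areas[sp] = level * ratio * canonical_total
            for sp, area in areas.items():
                if sigma > 0:
                    area *= rng.lognormal(mean=-sigma**2 / 2, sigma=sigma)
                rows.append(
                    {
                        "species": sp,
                        "replicate": rep,
                        "genotype": genotype,
                        "retention_time_min": _DEFAULT_RT.get(sp, 9.9),
                        "peak_area": area,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired transcript / protein expression tables
# ---------------------------------------------------------------------------

def simulate_expression_tables(
    n_genes: int,
    n_protein_down_mrna_stable: int,
    n_both_down: int,
    effect_log2fc: float = 1.0,
    p_signal: float = 1e-4,
    seed: int = 0,
    n_protein_up: int = 0,
    n_transcript_only_down: int = 0,
    n_transcript_up: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired transcript/protein tables with a configured overlap structure.

    Designated genes receive fold changes and p-values guaranteed to pass the
    downstream filters (protein fold change < 0.83 or > 1.20 with small
    p-value; transcript |log2FC| >= 1 for the transcript classes); all other
    genes are null (fold changes inside the unchanged band, uniform
    p-values).  Returns ``(transcripts, proteins, truth)`` where truth labels
    each gene's designed class.

    Transcript tables use log2 fold changes, protein tables linear
    mutant/control fold changes, mirroring the differing conventions of
    RNA-seq and TMT proteomics reports.
    """
    classes = {
        "protein_down_mrna_stable": n_protein_down_mrna_stable,
        "both_down": n_both_down,
        "protein_up": n_protein_up,
        "transcript_only_down": n_transcript_only_down,
        "transcript_up": n_transcript_up,
    }
    if any(v < 0 for v in classes.values()):
        raise TableError("class sizes must be non-negative")
    if sum(classes.values()) > n_genes:
        raise TableError("class sizes exceed n_genes")
    if not (0.0 < p_signal < 1.0):
        raise TableError("p_signal must be in (0, 1)")
    if effect_log2fc <= 0:
        raise TableError("effect_log2fc must be positive")

    rng = np.random.default_rng(seed)
    gene_ids = [f"AT{rng.integers(1, 6)}G{i:05d}" for i in range(1, n_genes + 1)]
    labels = np.array(["null"] * n_genes, dtype=object)
    start = 0
    for name, count in classes.items():
        labels[start : start + count] = name
        start += count

    eff = effect_log2fc
    # transcripts: null genes sit well inside the 2-fold band
    t_lfc = rng.normal(0.0, 0.2, size=n_genes).clip(-0.8, 0.8)
    t_p = rng.uniform(0.0, 1.0, size=n_genes)
    down_t = np.isin(labels, ["both_down", "transcript_only_down"])
    t_lfc[down_t] = -(eff + rng.exponential(0.3, size=int(down_t.sum()))).clip(min=1.0)
    t_p[down_t] = p_signal
    up_t = labels == "transcript_up"
    t_lfc[up_t] = (eff + rng.exponential(0.3, size=int(up_t.sum()))).clip(min=1.0)
    t_p[up_t] = p_signal

    # proteins: null genes inside (0.83, 1.20)
    p_fc = np.exp2(rng.normal(0.0, 0.1, size=n_genes).clip(-0.25, 0.25))
    p_p = rng.uniform(0.0, 1.0, size=n_genes)
    down_p = np.isin(labels, ["both_down", "protein_down_mrna_stable"])
    p_fc[down_p] = np.exp2(-(eff + rng.exponential(0.3, size=int(down_p.sum())))).clip(max=0.80)
    p_p[down_p] = p_signal
    up_p = labels == "protein_up"
    p_fc[up_p] = np.exp2(eff + rng.exponential(0.3, size=int(up_p.sum()))).clip(min=1.25)
    p_p[up_p] = p_signal

    transcripts = pd.DataFrame({"gene_id": gene_ids, "log2fc": t_lfc, "p_value": t_p})
    proteins = pd.DataFrame({"gene_id": gene_ids, "fold_change": p_fc, "p_value": p_p})
    truth = pd.DataFrame({"gene_id": gene_ids, "true_class": labels})
    return transcripts, proteins, truth


# ---------------------------------------------------------------------------
# Built-in demo reference set (synthetic sequences)
# ---------------------------------------------------------------------------

def demo_reference_genes() -> list[TRNAGene]:
    """Four synthetic mature tRNA references for demos and tests.

    The sequences are computer-generated 76-mers ending in the CCA tail, with a
    realistic anticodon placement (position 34) and conserved flanks; they
    are *not* database sequences.  tRNA-Ala genes (anticodons AGC, TGC, CGC)
    carry A at position 37 (m1I-pathway substrates); tRNA-Asp-GTC carries G37
    (m1G substrate).
    """
    return parse_trna_fasta(demo_reference_fasta())


def demo_reference_fasta() -> str:
    """FASTA text for :func:`demo_reference_genes` (deterministic)."""
    specs = [("Ala", "AGC", "A", 11), ("Ala", "TGC", "A", 23), ("Ala", "CGC", "A", 37), ("Asp", "GTC", "G", 51)]
    records = []
    for aa, anticodon, base37, salt in specs:
        rng = np.random.default_rng(salt)
        while True:
            body5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=31))  # offsets 0..30
            loop5 = "CT"                                                     # 31..32
            core = body5 + loop5 + anticodon + base37 + "A"                  # anticodon at 33..35
            body3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=76 - len(core) - 3))
            seq = core + body3 + "CCA"
            # anticodon must occur nearest position 34 at offset 33, uniquely decisive
            hits = [i for i in range(len(seq) - 2) if seq[i : i + 3] == anticodon]
            if min(hits, key=lambda off: (abs(off - 33), off)) == 33:
                records.append(f">tRNA-{aa}-{anticodon}-1-1 synthetic demo reference\n{seq}")
                break
    return "\n".join(records) + "\n"
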
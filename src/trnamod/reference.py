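"""Mature tRNA reference model and the anticodon-relative coordinate system.

A mature tRNA is represented by :class:`TRNAGene`, which locates the anticodon
(canonical positions 34-36) and defines "position 37" structurally as the base
immediately 3' of the anticodon (anticodon start + 3).  This is the site where
the two-step adenosine-to-inosine-to-N1-methylinosine pathway (TAD1 then TRM5)
and the N1-methylguanosine pathway operate.

Coordinates are 0-based half-open internally; every exported table reports
1-based positions.  Full Sprinzl numbering is deliberately not computed: for
mature references the anticodon-relative system is a bijection per gene and is
sufficient to name position 37.  tRNAs with insertions between the acceptor
stem and the anticodon would shift the absolute offset but not the label,
which is anchored on the located anticodon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from io import StringIO
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnticodonNotFoundError, FastaFormatError

__all__ = [
    "TRNAGene",
    "parse_trna_fasta",
    "canonical_position",
    "append_cca",
    "write_trna_fasta",
    "gene_index_frame",
]

#: GtRNAdb-style header token, e.g. ``tRNA-Ala-AGC-1-1`` or
#: ``Arabidopsis_thaliana_tRNA-iMet-CAT-1-1``.
_HEADER_RE = re.compile(r"tRNA-([A-Za-z]{2,4})-([ACGTUacgtu]{3})")

_MIN_LEN = 55
_MAX_LEN = 110


@dataclass(frozen=True)
class TRNAGene:
    """One mature tRNA reference with a located anticodon.

    Attributes
    ----------
    gene_id:
        Identifier taken from the FASTA header (first whitespace token).
    amino_acid:
        Three-letter amino-acid code from the header (``Ala``, ``Asp``, ...).
    anticodon:
        The anticodon trinucleotide as DNA (5'->3' on the tRNA sense strand).
    sequence:
        Mature sense-strand DNA (A/C/G/T), optionally CCA-appended.
    anticodon_offset:
        0-based index of the anticodon's first base (canonical position 34).
    has_cca:
        True when the sequence ends in the 3' CCA tail.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    anticodon_offset: int
    has_cca: bool

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (_MIN_LEN <= n <= _MAX_LEN):
            raise FastaFormatError(
                f"{self.gene_id}: sequence length {n} outside [{_MIN_LEN}, {_MAX_LEN}]"
            )
        if set(self.sequence) - set("ACGT"):
            raise FastaFormatError(f"{self.gene_id}: sequence is not plain A/C/G/T DNA")
        ac = self.anticodon_offset
        if self.sequence[ac : ac + 3] != self.anticodon:
            raise AnticodonNotFoundError(
                f"{self.gene_id}: anticodon {self.anticodon} not at offset {ac}"
            )
        if not (0 <= self.pos37_offset < n):
            raise FastaFormatError(f"{self.gene_id}: position 37 outside the sequence")
        if self.has_cca and not self.sequence.endswith("CCA"):
            raise FastaFormatError(f"{self.gene_id}: has_cca set but no 3' CCA")

    @property
    def pos37_offset(self) -> int:
        """0-based offset of canonical position 37 (anticodon start + 3)."""
        return self.anticodon_offset + 3

    @property
    def base37(self) -> str:
        """Reference base at position 37 (A for m1I-pathway substrates)."""
        return self.sequence[self.pos37_offset]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def _locate_anticodon(sequence: str, anticodon: str, hint_1based: int) -> int:
    """Offset of the anticodon occurrence whose 1-based start is nearest the
    hint; ties broken toward the smaller offset."""
    hits = [m.start() for m in re.finditer(f"(?={anticodon})", sequence)]
    if not hits:
        raise AnticodonNotFoundError(
            f"anticodon {anticodon} absent from sequence of length {len(sequence)}"
        )
    return min(hits, key=lambda off: (abs((off + 1) - hint_1based), off))


def parse_trna_fasta(
    fasta_text: str,
    anticodon_hint_position: int = 34,
    strip_introns: bool = False,
) -> list[TRNAGene]:
    """Parse GtRNAdb-style mature tRNA references.

    Headers must carry a ``tRNA-<AA>-<Anticodon>`` token.  U is mapped to T.
    Lowercase runs are treated as intron blocks: records containing them are
    rejected unless ``strip_introns`` is set, in which case the lowercase
    bases are removed and the mature sequence is kept.

    Parameters
    ----------
    fasta_text:
        FASTA content as a string.
    anticodon_hint_position:
        1-based position near which the anticodon is expected to start
        (canonical position 34).  Among all occurrences of the anticodon
        trinucleotide, the one whose start is nearest this hint is chosen;
        ties go to the smaller offset.
    strip_introns:
        Remove lowercase (intron) blocks instead of rejecting the record.
    """
    genes: list[TRNAGene] = []
    for record in SeqIO.parse(StringIO(fasta_text), "fasta"):
        header = record.description or record.id
        m = _HEADER_RE.search(header)
        if m is None:
            raise FastaFormatError(
                f"record {record.id!r}: header lacks a tRNA-<AA>-<Anticodon> token"
            )
        amino_acid, anticodon = m.group(1), m.group(2).upper().replace("U", "T")
        raw = str(record.seq)
        if any(c.islower() for c in raw):
            if not strip_introns:
                raise FastaFormatError(
                    f"record {record.id!r}: lowercase (intron) blocks present; "
                    "re-run with intron stripping to accept mature sequence"
                )
            raw = "".join(c for c in raw if not c.islower())
        seq = raw.upper().replace("U", "T")
        if set(seq) - set("ACGT"):
            raise FastaFormatError(f"record {record.id!r}: non-ACGTU characters")
        offset = _locate_anticodon(seq, anticodon, anticodon_hint_position)
        genes.append(
            TRNAGene(
                gene_id=record.id,
                amino_acid=amino_acid,
                anticodon=anticodon,
                sequence=seq,
                anticodon_offset=offset,
                has_cca=seq.endswith("CCA"),
            )
        )
    return genes


def canonical_position(gene: TRNAGene, offset: int) -> str:
    """Label a 0-based sequence offset in the anticodon-relative system.

    Anticodon bases map to ``"34"``/``"35"``/``"36"``, the base 3' of the
    anticodon to ``"37"``, and every other offset to ``"ac<signed distance>"``
    from the anticodon start (e.g. ``ac-1`` for position 33).  The mapping is
    a bijection per gene: ``ac+3`` never occurs because it is named ``37``.
    """
    if not (0 <= offset < len(gene.sequence)):
        raise IndexError(
            f"{gene.gene_id}: offset {offset} outside sequence of length {len(gene.sequence)}"
        )
    d = offset - gene.anticodon_offset
    if d in (0, 1, 2):
        return str(34 + d)
    if d == 3:
        return "37"
    return f"ac{d:+d}"


def append_cca(gene: TRNAGene) -> TRNAGene:
    """Return the gene with a 3' CCA tail appended (idempotent).

    Mature tRNAs carry the CCA end; simulated and aligned reads use the
    mature form.  Anticodon and position-37 offsets are unchanged.
    """
    if gene.has_cca:
        return gene
    return replace(gene, sequence=gene.sequence + "CCA", has_cca=True)


def write_trna_fasta(genes: Iterable[TRNAGene]) -> str:
    """Write genes back to FASTA (60-column wrap); round-trips with
    :func:`parse_trna_fasta`."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="") for g in genes
    ]
    out = StringIO()
    SeqIO.write(records, out, "fasta")
    return out.getvalue()


def gene_index_frame(genes: Iterable[TRNAGene]) -> pd.DataFrame:
    """Gene index as a table with 1-based anticodon/position-37 coordinates."""
    rows = [
        {
            "gene_id": g.gene_id,
            "amino_acid": g.amino_acid,
            "anticodon": g.anticodon,
            "length": len(g.sequence),
            "anticodon_start": g.anticodon_offset + 1,
            "position37": g.pos37_offset + 1,
        }
        for g in genes
    ]
    return pd.DataFrame(rows)
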
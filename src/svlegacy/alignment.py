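"""Column-indexed three-genome alignments.

A :class:`TripleAlignment` holds one chromosome of a whole-genome alignment of
two ingroup genomes (A, B) and one outgroup, as three gapped rows of equal
column count, plus per-row maps from alignment column to ungapped sequence
position.  All coordinates are 0-based, half-open; conversion to 1-based
happens only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

GAP = ord("-")

ROW_NAMES = ("ingroupA", "ingroupB", "outgroup")


@dataclass
class TripleAlignment:
    """Equal-length gapped rows for ingroup A, ingroup B and the outgroup."""

    chrom: str
    rows: tuple[str, str, str]
    names: tuple[str, str, str] = ROW_NAMES
    _arr: np.ndarray = field(init=False, repr=False)
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(self.rows) != 3:
            raise ValueError("expected 3 rows")
        if len(lengths) != 1:
            raise ValueError(f"unequal gapped lengths: {sorted(lengths)}")
        self._arr = np.array(
            [np.frombuffer(r.upper().encode(), dtype=np.uint8) for r in self.rows]
        )
        # _cum[r, c] = number of non-gap characters in row r strictly before column c
        nongap = (self._arr != GAP).astype(np.int64)
        self._cum = np.zeros((3, self.ncols + 1), dtype=np.int64)
        np.cumsum(nongap, axis=1, out=self._cum[:, 1:])

    @property
    def ncols(self) -> int:
        return self._arr.shape[1]

    @property
    def array(self) -> np.ndarray:
        """3 x ncols uint8 view of the alignment (gap = ord('-'))."""
        return self._arr

    def gap_mask(self) -> np.ndarray:
        return self._arr == GAP

    def col_to_seq_pos(self, row: int, col: int) -> int:
        """Ungapped position in row `row` of alignment column `col`.

        For a gap column this is the position of the next non-gap character
        (i.e. the insertion point), which makes [col_start, col_end) map to a
        half-open ungapped interval.
        """
        return int(self._cum[row, col])

    def seq_interval(self, row: int, col_start: int, col_end: int) -> tuple[int, int]:
        """Ungapped half-open interval of row `row` over a column interval."""
        return int(self._cum[row, col_start]), int(self._cum[row, col_end])

    def ungapped(self, row: int) -> str:
        return self.rows[row].replace("-", "")

    def slice_text(self, row: int, col_start: int, col_end: int) -> str:
        return self.rows[row][col_start:col_end]


def _from_records(chrom: str, seqs: list[str]) -> TripleAlignment:
    if len(seqs) != 3:
        raise ValueError(f"expected 3 rows, got {len(seqs)}")
    return TripleAlignment(chrom=chrom, rows=(seqs[0], seqs[1], seqs[2]))


def read_alignment(path, fmt: str = "fasta", chrom: str | None = None) -> TripleAlignment:
    """Read a three-row chromosome alignment.

    Parameters
    ----------
    path : str or Path
        Aligned multi-FASTA (one chromosome, 3 records), MAF, or XMFA
        (progressiveMauve output).
    fmt : {"fasta", "maf", "mauve"}
        File format, as understood by ``Bio.AlignIO``.  For "maf"/"mauve" the
        blocks are concatenated in reference (first-row) order.
    """
    if fmt == "fasta":
        aln = AlignIO.read(path, "fasta")
        if chrom is None:
            # headers written as ">rowname chrom"; fall back to the record id
            desc = aln[0].description.split()
            chrom = desc[1] if len(desc) > 1 else aln[0].id
        return _from_records(chrom, [str(rec.seq) for rec in aln])
    if fmt in ("maf", "mauve"):
        blocks = list(AlignIO.parse(path, fmt))
        if not blocks:
            raise ValueError("no alignment blocks found")
        for b in blocks:
            if len(b) != 3:
                raise ValueError(f"expected 3 rows per block, got {len(b)}")
        # concatenate blocks in reference order (start of the first row)
        def _start(block):
            ann = getattr(block[0], "annotations", {})
            return ann.get("start", 0)

        blocks.sort(key=_start)
        seqs = ["".join(str(b[i].seq) for b in blocks) for i in range(3)]
        name = chrom or blocks[0][0].id.split(".")[0]
        return _from_records(name, seqs)
    raise ValueError(f"unknown alignment format: {fmt!r}")


def write_alignment(aln: TripleAlignment, path) -> None:
    """Write a TripleAlignment as aligned multi-FASTA (3 records)."""
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name} {aln.chrom}\n")
            for i in range(0, len(row), 80):
                fh.write(row[i : i + 80] + "\n")
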
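"""Reference-anchored alignment handling and conservation scoring.

Alignments are kept as character matrices with an explicit map from column
index to reference residue numbering (column 1 -> ``ref_offset``, the first
residue of the edited alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .models import AMINO_ACIDS

GAP = "-"
DEFAULT_REF_OFFSET = 48

__all__ = [
    "MsaBundle",
    "strip_nonreference_columns",
    "column_frequencies",
    "conservation_scores",
    "read_protein_fasta",
    "write_protein_fasta",
]


@dataclass(frozen=True)
class MsaBundle:
    """Protein alignment with optional codon layer, tree, and numbering map.

    ``protein`` is an (n_seqs, n_cols) array of single characters;
    ``codon`` (optional) an (n_seqs, n_cols) array of 3-letter codons
    (``---`` for gaps) that translates to ``protein``.  ``positions`` gives
    the reference residue number of each column.
    """

    ids: tuple[str, ...]
    protein: np.ndarray
    codon: np.ndarray | None = None
    tree: str | None = None
    ref_id: str | None = None
    ref_offset: int = DEFAULT_REF_OFFSET
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        prot = np.asarray(self.protein, dtype="U1")
        if prot.ndim != 2:
            raise ValueError("protein alignment must be a 2-D character matrix")
        if len(self.ids) != prot.shape[0]:
            raise ValueError("one id required per alignment row")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "protein", prot)
        if self.codon is not None:
            cod = np.asarray(self.codon, dtype="U3")
            if cod.shape != prot.shape:
                raise ValueError("codon layer shape must match protein layer")
            object.__setattr__(self, "codon", cod)
            self._check_translation()
        if self.positions is None:
            pos = np.arange(self.ref_offset, self.ref_offset + prot.shape[1])
        else:
            pos = np.asarray(self.positions, dtype=int)
            if pos.size != prot.shape[1]:
                raise ValueError("positions must map every column")
        object.__setattr__(self, "positions", pos)

    def _check_translation(self) -> None:
        for r in range(self.n_seqs):
            for c in range(self.n_cols):
                codon = self.codon[r, c]
                aa = self.protein[r, c]
                if codon == "---":
                    if aa != GAP:
                        raise ValueError("codon gap without protein gap")
                    continue
                if str(Seq(codon).translate()) != aa:
                    raise ValueError(
                        f"codon {codon} at row {r} col {c} does not translate to {aa}"
                    )

    @property
    def n_seqs(self) -> int:
        return self.protein.shape[0]

    @property
    def n_cols(self) -> int:
        return self.protein.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        try:
            return self.protein[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def protein_sequences(self) -> dict[str, str]:
        return {i: "".join(row) for i, row in zip(self.ids, self.protein)}

    def codon_sequences(self) -> dict[str, str]:
        if self.codon is None:
            raise ValueError("bundle has no codon layer")
        return {i: "".join(row) for i, row in zip(self.ids, self.codon)}


def strip_nonreference_columns(
    msa: MsaBundle,
    ref_id: str | None = None,
    ref_offset: int | None = None,
) -> MsaBundle:
    """Drop every column where the reference sequence has a gap.

    The surviving columns are renumbered consecutively from ``ref_offset`` so
    column k corresponds to reference residue ``ref_offset + k``.  The codon
    layer, if present, is trimmed in register.
    """
    ref_id = ref_id if ref_id is not None else msa.ref_id
    if ref_id is None:
        raise KeyError("no reference id given")
    ref_offset = ref_offset if ref_offset is not None else msa.ref_offset
    ref_row = msa.row(ref_id)
    keep = ref_row != GAP
    if not keep.any():
        raise ValueError("reference sequence is all gaps")
    return replace(
        msa,
        protein=msa.protein[:, keep],
        codon=None if msa.codon is None else msa.codon[:, keep],
        ref_id=ref_id,
        ref_offset=ref_offset,
        positions=np.arange(ref_offset, ref_offset + int(keep.sum())),
    )


def column_frequencies(msa: MsaBundle) -> pd.DataFrame:
    """Per-column amino-acid frequencies over non-gap residues (logo layer).

    Columns of the result: one per amino acid, plus ``gap_fraction`` and
    ``scored`` (False for all-gap columns, whose frequencies are NaN).
    """
    aa_list = list(AMINO_ACIDS)
    records = []
    for c in range(msa.n_cols):
        col = msa.protein[:, c]
        nongap = col[np.isin(col, aa_list)]
        rec = {"position": int(msa.positions[c])}
        rec["gap_fraction"] = 1.0 - nongap.size / msa.n_seqs
        if nongap.size == 0:
            rec.update({aa: np.nan for aa in aa_list})
            rec["scored"] = False
        else:
            for aa in aa_list:
                rec[aa] = float((nongap == aa).sum() / nongap.size)
            rec["scored"] = True
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("position")


def conservation_scores(msa: MsaBundle) -> pd.DataFrame:
    """Normalized per-column conservation scores.

    Raw variability is the Shannon entropy (bits) of the non-gap residue
    frequencies.  Scores are z-normalized across scored columns so the mean
    is 0 and the population standard deviation is 1; lower scores mean more
    conserved, and invariant columns carry the column minimum.
    """
    freqs = column_frequencies(msa)
    scored = freqs[freqs["scored"]]
    if len(scored) < 2:
        raise ValueError("need >= 2 scored columns to normalize conservation")
    f = scored[list(AMINO_ACIDS)].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=1)
    sd = float(entropy.std())  # population SD
    if sd == 0:
        raise ValueError(
            "all columns have identical variability; conservation z-score undefined"
        )
    z = (entropy - entropy.mean()) / sd
    return pd.DataFrame(
        {"raw_variability": entropy, "conservation": z}, index=scored.index
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_protein_fasta(path: str | Path, **kwargs) -> MsaBundle:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(list(str(rec.seq).upper()))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    return MsaBundle(ids=tuple(ids), protein=np.array(rows, dtype="U1"), **kwargs)


def write_protein_fasta(msa: MsaBundle, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in msa.protein_sequences().items():
            fh.write(f">{seq_id}\n{seq}\n")
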
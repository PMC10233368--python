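"""Signal-peptide hydrophobicity analysis.

Per-residue Kyte-Doolittle hydropathy values, per-position group profiles
(mean +/- SEM across a set of signal peptides), substrate filtering by
SP/TMD/MTS annotation, and construction of N-terminal prefix-swap variants
and SP-only reporter fusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Kyte & Doolittle hydropathy scale, one value per standard amino acid.
# Spans -4.5 (Arg) to +4.5 (Ile).
KYTE_DOOLITTLE: Mapping[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

KD_MIN = min(KYTE_DOOLITTLE.values())
KD_MAX = max(KYTE_DOOLITTLE.values())

#: Preference categories a prey can be assigned by the screen.
CATEGORIES = ("no_interaction", "both", "prefers_A", "prefers_B", "excluded")


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the 20 standard amino acids."""


def kd_values(sequence: str) -> np.ndarray:
    """Map a protein sequence to its per-residue Kyte-Doolittle values.

    No window smoothing is applied: position ``i`` of the output is the
    scale value of residue ``i``.

    Parameters
    ----------
    sequence
        Non-empty string over the 20 standard one-letter amino acid codes.

    Raises
    ------
    InvalidResidueError
        Naming the offending character and its 1-based position.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    out = np.empty(len(sequence), dtype=float)
    for i, aa in enumerate(sequence):
        try:
            out[i] = KYTE_DOOLITTLE[aa]
        except KeyError:
            raise InvalidResidueError(
                f"invalid residue {aa!r} at position {i + 1}"
            ) from None
    return out


@dataclass
class HydropathyProfile:
    """Per-position hydropathy summary for a group of signal peptides.

    ``n[p]`` counts the sequences long enough to contribute at position
    ``p``; with variable-length input it is non-increasing along the
    profile.
    """

    label: str
    mean_kd: np.ndarray
    sem_kd: np.ndarray
    n: np.ndarray

    def __len__(self) -> int:
        return len(self.mean_kd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.label,
                "position": np.arange(1, len(self) + 1),
                "mean_kd": self.mean_kd,
                "sem_kd": self.sem_kd,
                "n": self.n,
            }
        )


def group_profile(
    sequences: Sequence[str],
    max_len: int = 25,
    label: str = "",
    window: int | None = None,
) -> HydropathyProfile:
    """Average Kyte-Doolittle hydropathy per position across a group of SPs.

    ``mean_kd(p)`` is the mean over all sequences of length >= p of the
    residue value at p; ``sem_kd(p)`` is the sample standard deviation
    (ddof=1) divided by sqrt(n(p)), reported as 0 where n(p) == 1.

    ``window``, if given, applies a centered moving average of that width
    to each sequence's value track before averaging. Off by default: the
    N-terminal positions 1-3 carry the biological signal of interest and
    smoothing would blur them.
    """
    if len(sequences) == 0:
        raise ValueError("group_profile requires at least one sequence")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tracks = []
    for seq in sequences:
        vals = kd_values(seq)
        if window is not None and window > 1:
            kernel = np.ones(window) / window
            vals = np.convolve(vals, kernel, mode="same")
        tracks.append(vals[:max_len])
    length = max(len(t) for t in tracks)
    stack = np.full((len(tracks), length), np.nan)
    for i, t in enumerate(tracks):
        stack[i, : len(t)] = t
    n = np.sum(~np.isnan(stack), axis=0)
    mean = np.nanmean(stack, axis=0)
    sd = np.zeros(length)
    multi = n > 1
    if np.any(multi):
        sd[multi] = np.nanstd(stack[:, multi], axis=0, ddof=1)
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return HydropathyProfile(label=label, mean_kd=mean, sem_kd=sem, n=n)


def profiles_by_group(
    groups: Mapping[str, Sequence[str]], max_len: int = 25, window: int | None = None
) -> pd.DataFrame:
    """Tidy table of :func:`group_profile` over several labelled groups."""
    frames = [
        group_profile(seqs, max_len=max_len, label=lab, window=window).to_frame()
        for lab, seqs in groups.items()
        if len(seqs) > 0
    ]
    if not frames:
        return pd.DataFrame(columns=["group", "position", "mean_kd", "sem_kd", "n"])
    return pd.concat(frames, ignore_index=True)


def swap_prefix(seq1: str, seq2: str, k: int = 3) -> tuple[str, str]:
    """Exchange the first ``k`` residues of two signal peptides.

    Models the N-terminal domain-swap construct pair: variant 1 carries
    seq2's prefix on seq1's body and vice versa. Lengths are preserved and
    applying the swap twice restores the originals.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(seq1) or k > len(seq2):
        raise ValueError(
            f"prefix length {k} exceeds a sequence length "
            f"({len(seq1)}, {len(seq2)})"
        )
    return seq2[:k] + seq1[k:], seq1[:k] + seq2[k:]


#: Fixed reporter body fused C-terminally to a signal peptide: a fluorescent
#: protein for visualization plus the biotin-acceptor peptide read out by
#: streptavidin.
REPORTER_BODY = ("mCherry", "AviTag")


@dataclass
class ReporterConstruct:
    """An SP-only reporter: a signal peptide fused to mCherry-AviTag.

    In simulation, a reporter prey inherits the planted translocon
    preference of the protein donating the SP (or, for prefix-swapped SPs,
    of the prefix donor).
    """

    sp_sequence: str
    donor_id: str | None = None
    body: tuple[str, ...] = field(default=REPORTER_BODY)

    @property
    def reporter_id(self) -> str:
        donor = self.donor_id or "sp"
        return f"{donor}-reporter"


def build_reporter(sp: str, donor_id: str | None = None) -> ReporterConstruct:
    """Build an SP-only reporter record from a signal peptide sequence."""
    if not sp:
        raise ValueError("signal peptide must be non-empty")
    kd_values(sp)  # validates residues
    return ReporterConstruct(sp_sequence=sp, donor_id=donor_id)


ANNOTATION_COLUMNS = ["protein_id", "has_sp", "has_tmd", "has_mts", "sp_sequence"]


def filter_substrates(
    pairs: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Flag candidate translocon substrates among preference calls.

    A prey is a candidate iff it has a signal peptide or a transmembrane
    domain (or both) and no predicted mitochondrial targeting signal —
    MTS-bearing proteins could be mitochondrial inner-membrane residents
    rather than ER substrates. Preys missing an annotation row are flagged
    (``annotation_missing``), never silently dropped, so candidates +
    non-candidates + missing always partition the input.
    """
    ann = annotations.set_index("protein_id")
    dup = ann.index[ann.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate annotation rows for: {dup}")
    out = pairs.copy()
    merged = out.join(ann, on="prey_id")
    missing = merged["has_sp"].isna()
    has_sp = merged["has_sp"].eq(True)  # NaN compares False
    has_tmd = merged["has_tmd"].eq(True)
    has_mts = merged["has_mts"].eq(True)
    candidate = (has_sp | has_tmd) & ~has_mts & ~missing
    out["has_sp"] = has_sp.to_numpy()
    out["has_tmd"] = has_tmd.to_numpy()
    out["has_mts"] = has_mts.to_numpy()
    out["sp_sequence"] = merged.get("sp_sequence", pd.Series(index=merged.index))
    out["annotation_missing"] = missing.to_numpy()
    out["is_candidate"] = candidate.to_numpy()
    return out


def substrate_counts(filtered: pd.DataFrame) -> pd.DataFrame:
    """Candidate counts per preference category from filter_substrates output."""
    return (
        filtered[filtered["is_candidate"]]
        .groupby("category", observed=True)
        .size()
        .rename("n_candidates")
        .reset_index()
    )
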
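"""Count-matrix I/O, multi-copy collapsing, cpm, TMM normalization and filtering.

The unit of analysis is a mature miRNA arm (5p or 3p); the container couples a
genes-by-samples integer count matrix with per-sample metadata (stage of the
reprogramming series and replicate/library-kit batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizationResult",
    "read_counts",
    "write_counts",
    "collapse_multicopy",
    "cpm",
    "tmm_factors",
    "filter_expressed",
]


class ParseError(ValueError):
    """Raised when a count/metadata table fails validation."""


@dataclass
class CountMatrix:
    """Raw integer counts (miRNA x sample) with per-sample stage/replicate labels.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integers; index = miRNA ids (unique), columns = sample ids.
    samples : DataFrame
        Indexed by sample id, with columns ``stage`` and ``replicate``; must
        cover exactly the columns of ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate miRNA ids: {dups}")
        if self.counts.columns.has_duplicates:
            raise ParseError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ParseError("non-numeric cells in count matrix")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ParseError(
                f"negative count at ({self.counts.index[g]}, {self.counts.columns[s]})"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(vals != np.round(vals))[0]
            raise ParseError(
                f"non-integer count at ({self.counts.index[g]}, {self.counts.columns[s]})"
            )
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ParseError(f"samples missing from metadata: {missing}")
        for col in ("stage", "replicate"):
            if col not in self.samples.columns:
                raise ParseError(f"sample metadata lacks required column '{col}'")
        # keep metadata aligned with (and restricted to) the matrix columns
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def mirna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample library size = column sum of raw counts."""
        return self.counts.sum(axis=0)

    @property
    def stages(self) -> pd.Series:
        return self.samples["stage"]

    @property
    def replicates(self) -> pd.Series:
        return self.samples["replicate"]

    def subset(self, mirnas=None, samples=None) -> "CountMatrix":
        counts = self.counts
        if mirnas is not None:
            counts = counts.loc[mirnas]
        if samples is not None:
            counts = counts[samples]
        return CountMatrix(counts, self.samples.loc[counts.columns])


@dataclass
class NormalizationResult:
    """TMM scaling factors, rescaled to geometric mean 1."""

    factors: pd.Series
    ref_sample: str
    trim_M: float = 0.30
    trim_A: float = 0.05
    lib_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def read_counts(path, samples_path=None) -> CountMatrix:
    """Read a TSV count matrix (+ companion sample-metadata TSV).

    The matrix has a header row of sample ids and a first column of miRNA ids.
    The metadata table has columns sample_id, stage, replicate.
    """
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    # locate offending cells with a line number for the error message
    for i, (mirna, row) in enumerate(counts.iterrows()):
        for s, v in row.items():
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise ParseError(f"{path}:{i + 2}: non-numeric cell ({mirna}, {s}): {v!r}")
            if fv < 0:
                raise ParseError(f"{path}:{i + 2}: negative count ({mirna}, {s}): {v}")
            if fv != int(fv):
                raise ParseError(f"{path}:{i + 2}: non-integer count ({mirna}, {s}): {v}")
    counts = counts.astype(np.int64)
    if samples_path is None:
        samples_path = path.with_name(path.stem + ".samples.tsv")
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    missing = [s for s in counts.columns if s not in samples.index]
    if missing:
        raise ParseError(f"{samples_path}: missing metadata for samples {missing}")
    return CountMatrix(counts, samples)


def write_counts(cm: CountMatrix, path, samples_path=None) -> None:
    path = Path(path)
    cm.counts.to_csv(path, sep="\t", index_label="mirna_id")
    if samples_path is None:
        samples_path = path.with_name(path.stem + ".samples.tsv")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def collapse_multicopy(cm: CountMatrix, groups: Mapping[str, str]) -> CountMatrix:
    """Sum rows of multi-copy miRNAs sharing one mature sequence.

    ``groups`` maps each per-locus id (e.g. miR-9-1-5p) to its collapsed id
    (miR-9-5p). Ungrouped rows pass through unchanged; total counts are
    conserved.
    """
    missing = [m for m in groups if m not in cm.counts.index]
    if missing:
        raise KeyError(f"grouped ids absent from count matrix: {missing}")
    targets = set(groups.values())
    ungrouped = [m for m in cm.counts.index if m not in groups]
    collide = targets.intersection(ungrouped)
    if collide:
        raise ValueError(f"collapsed ids collide with existing ungrouped ids: {sorted(collide)}")
    new_id = pd.Index([groups.get(m, m) for m in cm.counts.index])
    collapsed = cm.counts.groupby(new_id, sort=False).sum()
    # preserve first-appearance order
    order = pd.unique(new_id)
    collapsed = collapsed.loc[order]
    return CountMatrix(collapsed, cm.samples)


def cpm(cm: CountMatrix, log2: bool = False, prior: float = 0.5,
        lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; optionally log2 with a pseudo-count prior.

    With ``log2=True`` the value is
    ``log2((count + prior) / (lib_size + 2*prior) * 1e6)`` so all-zero rows
    stay finite. ``lib_sizes`` may be TMM-effective sizes; defaults to raw
    column sums.
    """
    libs = cm.lib_sizes if lib_sizes is None else lib_sizes.loc[cm.sample_ids]
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"zero/negative library size for samples {bad}")
    counts = cm.counts.to_numpy(dtype=float)
    if log2:
        vals = np.log2((counts + prior) / (libs.to_numpy() + 2.0 * prior) * 1e6)
    else:
        vals = counts / libs.to_numpy() * 1e6
    return pd.DataFrame(vals, index=cm.mirna_ids, columns=cm.sample_ids)


def _choose_reference(cm: CountMatrix) -> str:
    """Library whose 75th-percentile cpm is closest to the mean upper quartile."""
    x = cpm(cm)
    uq = np.array([np.percentile(x[s][x[s] > 0], 75) if (x[s] > 0).any() else 0.0
                   for s in cm.sample_ids])
    return str(cm.sample_ids[np.argmin(np.abs(uq - uq.mean()))])


def tmm_factors(cm: CountMatrix, ref: str = "auto",
                trim_M: float = 0.30, trim_A: float = 0.05) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling factors.

    For each library against the reference, per-gene log2 expression ratios
    M and average log2 abundances A are computed over genes expressed in
    both; after trimming the most extreme ``trim_M`` of M (each tail) and
    ``trim_A`` of A, the factor is 2 to the inverse-variance-weighted mean M.
    Factors are rescaled to geometric mean 1.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    ref_sample = _choose_reference(cm) if ref == "auto" else ref
    if ref_sample not in cm.sample_ids:
        raise KeyError(f"unknown reference sample {ref_sample!r}")
    libs = cm.lib_sizes.astype(float)
    y_ref = cm.counts[ref_sample].to_numpy(dtype=float)
    n_ref = float(libs[ref_sample])
    factors = {}
    for s in cm.sample_ids:
        y = cm.counts[s].to_numpy(dtype=float)
        n = float(libs[s])
        both = (y > 0) & (y_ref > 0)
        if not both.any():
            raise ValueError(f"sample {s!r} shares no expressed genes with reference")
        yk, yr = y[both], y_ref[both]
        M = np.log2((yk / n) / (yr / n_ref))
        A = 0.5 * np.log2((yk / n) * (yr / n_ref))
        w = (n - yk) / (n * yk) + (n_ref - yr) / (n_ref * yr)
        if np.abs(M).max() < 1e-10:  # identical relative composition
            factors[s] = 1.0
            continue
        ng = M.size
        lo_m = np.floor(ng * trim_M) + 1
        hi_m = ng + 1 - lo_m
        lo_a = np.floor(ng * trim_A) + 1
        hi_a = ng + 1 - lo_a
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[s] = float(2.0 ** f)
    fac = pd.Series(factors).loc[cm.sample_ids]
    fac = fac / np.exp(np.mean(np.log(fac)))
    return NormalizationResult(factors=fac, ref_sample=ref_sample,
                               trim_M=trim_M, trim_A=trim_A, lib_sizes=libs)


def filter_expressed(cm: CountMatrix, min_cpm: float = 4.0) -> CountMatrix:
    """Keep miRNAs with >= ``min_cpm`` cpm in >=1 library of *every* replicate group.

    This is the abundance rule used before differential expression: a miRNA
    must be detectably expressed in each biological replicate (library kit)
    to count as present, but only in one library per replicate.
    """
    x = cpm(cm)
    keep = np.ones(len(cm.mirna_ids), dtype=bool)
    for _, grp in cm.samples.groupby("replicate"):
        cols = grp.index
        keep &= (x[cols] >= min_cpm).any(axis=1).to_numpy()
    return cm.subset(mirnas=cm.mirna_ids[keep])
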
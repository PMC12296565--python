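"""Kimura two-parameter (K2P) distances and barcode-gap evaluation.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T) and transversions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

where P and Q are the transition and transversion proportions over the sites
comparable between the two sequences. Sites where either sequence carries a
gap, N or any IUPAC ambiguity are excluded pairwise ("gaps treated as missing
data", pairwise deletion). When the logarithm argument is non-positive the
distance is saturated and reported as undefined rather than a number.

A marker discriminates species under the barcode-gap rule when mean
interspecific distance exceeds r times mean intraspecific distance
(classically r = 10; the operational criterion used for these markers is
r = 5).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .alignio import LabeledAlignment

# Encoding: A,C,G,T -> 0..3, anything else (gap/N/ambiguity) -> 4 (missing).
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes (4 = missing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclasses.dataclass(frozen=True)
class PairwiseDistance:
    """K2P result for one sequence pair.

    ``d`` is None when the distance is undefined (saturation or no
    comparable sites); ``reason`` then says why.
    """

    idA: str
    idB: str
    P: float
    Q: float
    n_valid: int
    d: float | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.d is not None


def _k2p_from_counts(ts: int, tv: int, n_valid: int) -> tuple[float, float, float | None, str | None]:
    if n_valid == 0:
        return 0.0, 0.0, None, "no comparable sites"
    P = ts / n_valid
    Q = tv / n_valid
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return P, Q, None, "saturated (log argument <= 0)"
    return P, Q, -0.5 * math.log(a * math.sqrt(b)), None


def k2p_distance(seqA: str, seqB: str, idA: str = "A", idB: str = "B") -> PairwiseDistance:
    """K2P distance between two aligned sequences (pairwise deletion)."""
    if len(seqA) != len(seqB):
        raise ValueError(f"sequences differ in length ({len(seqA)} vs {len(seqB)})")
    a = encode(seqA)
    b = encode(seqB)
    valid = (a < 4) & (b < 4)
    n_valid = int(valid.sum())
    diff = valid & (a != b)
    # Purines (A=0, G=2) have even codes, pyrimidines odd: a change within a
    # parity class is a transition, across classes a transversion.
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    P, Q, d, reason = _k2p_from_counts(ts, tv, n_valid)
    return PairwiseDistance(idA=idA, idB=idB, P=P, Q=Q, n_valid=n_valid, d=d, reason=reason)


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-cell undefined flags.

    ``d`` holds NaN where a pair is undefined; ``P``, ``Q`` and ``n_valid``
    are always populated from the site recount.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    n_valid: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in itertools.combinations(range(self.n), 2):
            if np.isnan(self.d[i, j]):
                out.append((self.ids[i], self.ids[j]))
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in itertools.combinations(range(self.n), 2):
            rows.append(
                {
                    "idA": self.ids[i],
                    "idB": self.ids[j],
                    "d": self.d[i, j],
                    "P": self.P[i, j],
                    "Q": self.Q[i, j],
                    "n_valid": int(self.n_valid[i, j]),
                    "flag": "undefined" if np.isnan(self.d[i, j]) else "ok",
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long_frame().to_csv(path, sep="\t", index=False)
        return path

    def write_phylip(self, path: str | Path) -> Path:
        """Square PHYLIP matrix; undefined cells written as -1.0."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, rid in enumerate(self.ids):
                cells = " ".join(
                    f"{(-1.0 if np.isnan(x) else x):.6f}" for x in self.d[i]
                )
                fh.write(f"{rid[:10]:<10} {cells}\n")
        return path


def distance_matrix(aln: LabeledAlignment) -> DistanceMatrix:
    """All-pairs K2P matrix (symmetric, zero diagonal).

    Undefined pairs are flagged with NaN; the matrix is never aborted by a
    single saturated cell.
    """
    if aln.n < 2:
        raise ValueError("distance matrix needs at least 2 sequences")
    codes = np.stack([encode(s) for s in aln.seqs])  # (n, L)
    n = aln.n
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    nv = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(nv, int((codes[0] < 4).sum()))
    for i in range(n):
        nv[i, i] = int((codes[i] < 4).sum())
    for i, j in itertools.combinations(range(n), 2):
        a, b = codes[i], codes[j]
        valid = (a < 4) & (b < 4)
        diff = valid & (a != b)
        ts = int((diff & ((a & 1) == (b & 1))).sum())
        tv = int(diff.sum()) - ts
        nvij = int(valid.sum())
        p, q, dist, _ = _k2p_from_counts(ts, tv, nvij)
        P[i, j] = P[j, i] = p
        Q[i, j] = Q[j, i] = q
        nv[i, j] = nv[j, i] = nvij
        d[i, j] = d[j, i] = np.nan if dist is None else dist
    return DistanceMatrix(ids=aln.ids, d=d, P=P, Q=Q, n_valid=nv)


def _stats(values: list[float]) -> dict[str, float | int]:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n_pairs": int(arr.size),
    }


@dataclasses.dataclass(frozen=True)
class DistanceSummary:
    """Per-marker intra/interspecific distance summary.

    ``inter_mean`` averages the per-species-pair means (the headline
    convention; printed interspecific ranges read as ranges over species
    pairs). ``inter_mean_pooled`` pools every heterospecific pair instead;
    both are reported.
    """

    marker: str
    intra_by_species: dict[str, dict]
    inter_by_pair: dict[tuple[str, str], dict]
    intra_mean: float
    inter_mean: float
    inter_mean_pooled: float
    intra_range: tuple[float, float]
    inter_range: tuple[float, float]
    n_undefined: int
    warnings: tuple[str, ...] = ()

    @property
    def gap_ratio(self) -> float:
        """inter_mean / intra_mean; +inf when intra_mean is zero."""
        if self.intra_mean == 0.0:
            return math.inf
        return self.inter_mean / self.intra_mean


def summarize_distances(dm: DistanceMatrix, species: list[str | None], marker: str = "other") -> DistanceSummary:
    """Summarize a distance matrix by species labels.

    Intraspecific distances pool all conspecific pairs; interspecific
    statistics are computed per species pair, with the headline inter mean
    and range taken over species-pair means. Undefined cells are excluded
    from every statistic (their count is reported).
    """
    if len(species) != dm.n:
        raise ValueError("species labels must match matrix dimension")
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    n_undef = 0
    for i, j in itertools.combinations(range(dm.n), 2):
        si, sj = species[i], species[j]
        if si is None or sj is None:
            continue
        val = dm.d[i, j]
        if np.isnan(val):
            n_undef += 1
            continue
        if si == sj:
            intra.setdefault(si, []).append(float(val))
        else:
            key = tuple(sorted((si, sj)))
            inter.setdefault(key, []).append(float(val))
    warnings = []
    if not intra:
        warnings.append("no conspecific pairs with defined distances")
    if not inter:
        warnings.append("no heterospecific pairs with defined distances")
    intra_all = [v for vs in intra.values() for v in vs]
    inter_all = [v for vs in inter.values() for v in vs]
    pair_means = [float(np.mean(vs)) for vs in inter.values()]
    return DistanceSummary(
        marker=marker,
        intra_by_species={sp: _stats(vs) for sp, vs in sorted(intra.items())},
        inter_by_pair={pair: _stats(vs) for pair, vs in sorted(inter.items())},
        intra_mean=float(np.mean(intra_all)) if intra_all else math.nan,
        inter_mean=float(np.mean(pair_means)) if pair_means else math.nan,
        inter_mean_pooled=float(np.mean(inter_all)) if inter_all else math.nan,
        intra_range=(min(intra_all), max(intra_all)) if intra_all else (math.nan, math.nan),
        inter_range=(min(pair_means), max(pair_means)) if pair_means else (math.nan, math.nan),
        n_undefined=n_undef,
        warnings=tuple(warnings),
    )


@dataclasses.dataclass(frozen=True)
class GapVerdict:
    """Barcode-gap verdict at threshold r: passes iff gap_ratio >= r."""

    marker: str
    gap_ratio: float
    threshold: float
    passes: bool
    note: str


def barcode_gap(summary: DistanceSummary, r: float = 10.0) -> GapVerdict:
    """Apply the barcode-gap rule at threshold ``r`` (default the 10x rule)."""
    if r <= 0:
        raise ValueError("threshold r must be positive")
    ratio = summary.gap_ratio
    if math.isinf(ratio):
        note = f"infinite ratio (intra_mean = 0), passes at any r (r={r})"
        return GapVerdict(summary.marker, ratio, r, True, note)
    passes = ratio >= r
    note = f"inter_mean/intra_mean = {ratio:.2f} vs r = {r}"
    return GapVerdict(summary.marker, ratio, r, passes, note)


def compare_marker_distances(*groups: list[float]) -> dict[str, float | str | None]:
    """Compare distance distributions between markers.

    Two groups: two-sided Welch t-test plus Kruskal-Wallis; three or more:
    Kruskal-Wallis only (t-statistics set to None). Identical constant
    groups degenerate to p = 1 with a note.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    note = None
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        note = "degenerate: zero variance in all groups"
        t_stat: float | None = 0.0 if len(groups) == 2 else None
        t_p: float | None = 1.0 if len(groups) == 2 else None
        return {
            "t_statistic": t_stat, "t_p": t_p,
            "kruskal_H": 0.0, "kruskal_p": 1.0, "note": note,
        }
    t_stat = t_p = None
    if len(groups) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        t_stat, t_p = float(res.statistic), float(res.pvalue)
        if math.isnan(t_stat):  # both groups constant but unequal
            t_stat, t_p = math.inf, 0.0
            note = "degenerate variance in both groups"
    kw = stats.kruskal(*arrays)
    return {
        "t_statistic": t_stat,
        "t_p": t_p,
        "kruskal_H": float(kw.statistic),
        "kruskal_p": float(kw.pvalue),
        "note": note,
    }
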
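"""Wavelet-packet decomposition and subband-energy texture descriptors.

The analysis uses a catalogue of 53 wavelet filter banks spanning six
families (Haar, Daubechies, symlets, coiflets, biorthogonal, reverse
biorthogonal), a full separable 2-D wavelet packet transform to depth 3, and
a 12-feature energy descriptor per decomposed branch.  With three iterations
the packet tree has 1 + 4 + 16 = 21 internal (decomposed) branches, hence a
21 x 12 = 252-component feature vector per image and base.

Boundary handling is periodization (wrap-around), so every level decimates a
size-n axis to ceil(n/2), Parseval's identity holds exactly for the
orthogonal families, and depth-3 trees are well defined for any even-ish
input.  Subband energy is the plain sum of absolute coefficient values; no
normalization by sub-image area is applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt

QUADRANTS = ("LL", "LH", "HL", "HH")

_BIOR_SUFFIXES = (
    "1.1", "1.3", "1.5", "2.2", "2.4", "2.6", "2.8",
    "3.1", "3.3", "3.5", "3.7", "3.9", "4.4", "5.5", "6.8",
)

#: id -> (pywt name, family); ids 1 and 2 are the same filter under two
#: catalogue entries (Haar == db1), both kept to preserve the numbering.
WAVELET_CATALOGUE: dict[int, tuple[str, str]] = {1: ("haar", "Haar")}
WAVELET_CATALOGUE.update({i: (f"db{i - 1}", "Daubechies") for i in range(2, 12)})
WAVELET_CATALOGUE.update({i: (f"sym{i - 10}", "Symlet") for i in range(12, 19)})
WAVELET_CATALOGUE.update({i: (f"coif{i - 18}", "Coiflet") for i in range(19, 24)})
WAVELET_CATALOGUE.update(
    {24 + k: (f"bior{s}", "Biorthogonal") for k, s in enumerate(_BIOR_SUFFIXES)}
)
WAVELET_CATALOGUE.update(
    {39 + k: (f"rbio{s}", "ReverseBiorthogonal") for k, s in enumerate(_BIOR_SUFFIXES)}
)

N_BASES = len(WAVELET_CATALOGUE)  # 53

#: depth-3 tree bookkeeping: 21 internal branches, 12 features each
N_BRANCHES = 21
N_FEATURES_PER_BRANCH = 12
FEATURE_LENGTH = N_BRANCHES * N_FEATURES_PER_BRANCH


@dataclass(frozen=True)
class WaveletBase:
    """One catalogued filter bank: analysis and synthesis filter pairs."""

    wavelet_id: int
    family: str
    name: str
    dec_lo: tuple[float, ...]
    dec_hi: tuple[float, ...]
    rec_lo: tuple[float, ...]
    rec_hi: tuple[float, ...]

    @property
    def is_orthogonal(self) -> bool:
        return self.family in ("Haar", "Daubechies", "Symlet", "Coiflet")


def get_wavelet_base(wavelet_id: int) -> WaveletBase:
    """Return the catalogued base for an id in 1..53."""
    try:
        name, family = WAVELET_CATALOGUE[wavelet_id]
    except KeyError:
        raise ValueError(f"wavelet_id must be in 1..{N_BASES}, got {wavelet_id}") from None
    w = pywt.Wavelet(name)
    return WaveletBase(
        wavelet_id=wavelet_id,
        family=family,
        name=name,
        dec_lo=tuple(w.dec_lo),
        dec_hi=tuple(w.dec_hi),
        rec_lo=tuple(w.rec_lo),
        rec_hi=tuple(w.rec_hi),
    )


def dwt2_step(img: np.ndarray, base: WaveletBase) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One separable analysis step: (LL, LH, HL, HH), each ceil(n/2) x ceil(m/2).

    Rows are filtered and decimated with (dec_lo | dec_hi), then columns;
    LL carries the approximation.  Periodized boundaries.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D coefficient matrix")
    if min(img.shape) < 2:
        raise ValueError(f"image {img.shape} too small to decompose")
    ll, (lh, hl, hh) = pywt.dwt2(img, pywt.Wavelet(base.name), mode="periodization")
    return ll, lh, hl, hh


def idwt2_step(
    bands: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray], base: WaveletBase
) -> np.ndarray:
    """Inverse of :func:`dwt2_step` using the synthesis pair (rec_lo, rec_hi)."""
    ll, lh, hl, hh = bands
    return pywt.idwt2((ll, (lh, hl, hh)), pywt.Wavelet(base.name), mode="periodization")


@dataclass(frozen=True)
class WPTNode:
    """A node of the packet tree: quadrant path from the root plus its sub-image."""

    path: tuple[str, ...]
    subimage: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.path)


def wpt_decompose(img: np.ndarray, base: WaveletBase, depth: int = 3) -> list[WPTNode]:
    """Full wavelet packet tree: every node above ``depth`` gets four children.

    Returns all nodes in breadth-first order (root first, children always
    LL, LH, HL, HH).  At depth 3 there are 85 nodes, 21 of them internal.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    nodes = [WPTNode(path=(), subimage=np.asarray(img, dtype=float))]
    frontier = nodes[:]
    for _ in range(depth):
        next_frontier = []
        for node in frontier:
            children = dwt2_step(node.subimage, base)
            for quad, sub in zip(QUADRANTS, children):
                child = WPTNode(path=node.path + (quad,), subimage=sub)
                nodes.append(child)
                next_frontier.append(child)
        frontier = next_frontier
    return nodes


def internal_nodes(nodes: list[WPTNode], depth: int = 3) -> list[WPTNode]:
    """The decomposed branches, breadth-first: all nodes above the leaf depth."""
    out = [n for n in nodes if n.depth < depth]
    out.sort(key=lambda n: (n.depth, tuple(QUADRANTS.index(q) for q in n.path)))
    return out


_FRAC_EPS = 1e-12


def branch_features(
    children: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
) -> np.ndarray:
    """12 energy features of one branch: e, e/e_max, e/sum(others).

    e_i is the sum of absolute coefficient values of child i (order LL, LH,
    HL, HH).  Degenerate branches: if every e_i is zero all 12 features are
    zero; if the complementary sum for a nonzero e_i is zero the fractional
    ratio is e_i / 1e-12 (deterministic and monotone in e_i).
    """
    e = np.array([np.abs(np.asarray(c, dtype=float)).sum() for c in children])
    e_max = e.max()
    if e_max == 0.0:
        return np.zeros(12)
    max_ratio = e / e_max
    rest = e.sum() - e
    frac_ratio = np.where(rest > 0.0, e / np.where(rest > 0.0, rest, 1.0), e / _FRAC_EPS)
    frac_ratio[e == 0.0] = 0.0
    return np.concatenate([e, max_ratio, frac_ratio])


def feature_vector(img: np.ndarray, base: WaveletBase, depth: int = 3) -> np.ndarray:
    """The 252-component descriptor: branch_features over the 21 internal nodes.

    Branch order is breadth-first (root; depth-1 LL, LH, HL, HH; depth-2
    parent-major), children always LL, LH, HL, HH; within a branch the 12
    features are e[4], max_ratio[4], frac_ratio[4].
    """
    nodes = wpt_decompose(img, base, depth=depth)
    by_path = {n.path: n for n in nodes}
    feats = []
    for node in internal_nodes(nodes, depth=depth):
        children = tuple(by_path[node.path + (q,)].subimage for q in QUADRANTS)
        feats.append(branch_features(children))
    return np.concatenate(feats)


def feature_names(depth: int = 3) -> list[str]:
    """Column names branch{b}_{e|maxr|fracr}{1..4} in feature-vector order."""
    n_internal = sum(4 ** d for d in range(depth))
    names = []
    for b in range(n_internal):
        for feat in ("e", "maxr", "fracr"):
            names.extend(f"branch{b}_{feat}{i}" for i in range(1, 5))
    return names


def write_feature_matrix(
    path: str | Path, matrix: np.ndarray, labels: np.ndarray, depth: int = 3
) -> None:
    """CSV writer: one row per image, named feature columns plus a label column."""
    names = feature_names(depth)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != len(names):
        raise ValueError(f"expected {len(names)} columns, got {matrix.shape[1]}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(names + ["label"])
        for row, y in zip(matrix, labels):
            writer.writerow([repr(float(v)) for v in row] + [int(y)])


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a feature CSV back into (matrix, labels)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[-1] != "label":
            raise ValueError("feature CSV must end with a label column")
        rows, labels = [], []
        for row in reader:
            rows.append([float(v) for v in row[:-1]])
            labels.append(int(row[-1]))
    return np.array(rows), np.array(labels)
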
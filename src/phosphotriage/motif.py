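"""Kinase consensus-motif parsing, matching and positional enrichment.

A motif is a set of positional constraints relative to the phosphoacceptor
(position 0, index 7 of a 15-mer window): per position an *allowed* residue
set (empty = any residue) and a *forbidden* set.  The notation follows the
square-bracket / brace convention used for the ULK1 consensus:

    [M/L/Q/F]-{P}-{P}-[S/T]-[Y/I/M/S/F/V/W]{P}-[Y/S/H/I/W/M]{P}

where ``[...]`` lists conforming residues, ``{...}`` non-conforming ones,
``-`` separates positions, and juxtaposed groups at one position are a
conjunction.  Position 0 is the (first) group whose allowed set is a
subset of {S, T}.

Positional enrichment matrices (log2 foreground/background frequency
ratios with a pseudocount) summarize the sequence context of a site set
relative to a background set, the matrix form of a consensus logo.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, CENTER_INDEX, PAD, WINDOW_LENGTH

#: ULK1 substrate consensus, positions -3..+2 around the phosphoacceptor.
ULK1_MOTIF = "[M/L/Q/F]-{P}-{P}-[S/T]-[Y/I/M/S/F/V/W]{P}-[Y/S/H/I/W/M]{P}"

_AA_SET = frozenset(AMINO_ACIDS)
# unicode hyphen/dash variants accepted as position separators
_SEPARATORS = "-‐‑‒–—"
_GROUP_RE = re.compile(r"\[([^\[\]{}]*)\]|\{([^\[\]{}]*)\}")


class MotifParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPosition:
    """Constraint at one position: allowed set (empty = any) and forbidden set."""

    allowed: frozenset
    forbidden: frozenset

    def accepts(self, ch: str) -> bool:
        # Pad characters can never satisfy an allowed-set constraint but do
        # pass a forbidden-only position.
        if self.allowed and ch not in self.allowed:
            return False
        return ch not in self.forbidden


@dataclass(frozen=True)
class Motif:
    """Positional residue constraints keyed by offset from the phosphoacceptor."""

    positions: Mapping[int, MotifPosition]

    def __post_init__(self):
        object.__setattr__(self, "positions", MappingProxyType(dict(self.positions)))
        for off, pos in self.positions.items():
            if pos.allowed & pos.forbidden:
                raise ValueError(f"position {off}: allowed and forbidden sets overlap")
        center = self.positions.get(0)
        if center is not None and center.allowed and not center.allowed <= {"S", "T"}:
            raise ValueError("position-0 allowed set must be a subset of {S, T}")

    def __eq__(self, other):
        if not isinstance(other, Motif):
            return NotImplemented
        return dict(self.positions) == dict(other.positions)

    def __hash__(self):
        return hash(tuple(sorted(self.positions.items(), key=lambda kv: kv[0])))

    @property
    def span(self) -> Tuple[int, int]:
        offs = sorted(self.positions)
        return offs[0], offs[-1]


def _parse_residues(body: str, token: str) -> frozenset:
    letters = [c for c in body.replace("/", "").replace(",", "") if not c.isspace()]
    bad = [c for c in letters if c not in _AA_SET]
    if bad:
        raise MotifParseError(f"unknown residue letter {bad[0]!r} in group {token!r}")
    return frozenset(letters)


def parse_motif(notation: str, anchor: int | None = None) -> Motif:
    """Parse bracket/brace motif notation into a :class:`Motif`.

    ``anchor`` gives the index (0-based, left to right) of the token that
    sits at position 0.  When omitted, the first token whose allowed set is
    non-empty and within {S, T} is used; if no such token exists the
    notation is ambiguous and a :class:`MotifParseError` is raised.
    """
    text = notation.strip()
    for sep in _SEPARATORS[1:]:
        text = text.replace(sep, "-")
    if not text:
        raise MotifParseError("empty motif notation")
    tokens = [t.strip() for t in text.split("-")]
    if any(not t for t in tokens):
        raise MotifParseError(f"empty position token in {notation!r}")

    parsed: list[MotifPosition] = []
    for token in tokens:
        allowed: set = set()
        forbidden: set = set()
        consumed = 0
        for m in _GROUP_RE.finditer(token):
            if m.start() != consumed:
                raise MotifParseError(f"malformed group syntax in token {token!r}")
            consumed = m.end()
            if m.group(1) is not None:
                allowed |= _parse_residues(m.group(1), token)
            else:
                forbidden |= _parse_residues(m.group(2), token)
        if consumed != len(token):
            raise MotifParseError(f"unbalanced brackets in token {token!r}")
        if allowed & forbidden:
            raise MotifParseError(f"allowed/forbidden overlap in token {token!r}")
        parsed.append(MotifPosition(frozenset(allowed), frozenset(forbidden)))

    if anchor is None:
        candidates = [
            i for i, p in enumerate(parsed) if p.allowed and p.allowed <= {"S", "T"}
        ]
        if not candidates:
            raise MotifParseError(
                "no position-0 group (allowed subset of {S,T}); pass anchor= explicitly"
            )
        anchor = candidates[0]
    # anchor may lie outside the token range: a fragment such as
    # "[M/L/Q/F]-{P}" with anchor=3 constrains positions -3 and -2 only
    return Motif({i - anchor: pos for i, pos in enumerate(parsed)})


def serialize_motif(motif: Motif) -> str:
    """Inverse of :func:`parse_motif` (same anchor): bracket/brace notation."""
    lo, hi = motif.span
    tokens = []
    for off in range(lo, hi + 1):
        pos = motif.positions.get(off, MotifPosition(frozenset(), frozenset()))
        token = ""
        if pos.allowed:
            token += "[" + "/".join(sorted(pos.allowed)) + "]"
        if pos.forbidden:
            token += "{" + "/".join(sorted(pos.forbidden)) + "}"
        tokens.append(token if token else "[]")
    return "-".join(tokens)


def match(motif: Motif, window: str) -> bool:
    """True iff every motif position accepts the corresponding window residue.

    The window must be a 15-mer; motif offsets are taken relative to the
    centre (index 7 = position 0).  The terminal pad character never
    satisfies an allowed set but does pass a forbidden-only position.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"window must have length {WINDOW_LENGTH}, got {len(window)}")
    for off, pos in motif.positions.items():
        idx = CENTER_INDEX + off
        if idx < 0 or idx >= WINDOW_LENGTH:
            raise ValueError(f"motif offset {off} falls outside the window")
        if not pos.accepts(window[idx]):
            return False
    return True


def match_windows(motif: Motif, windows: Iterable[str]) -> np.ndarray:
    """Vector of :func:`match` results over an iterable of windows."""
    return np.fromiter((match(motif, w) for w in windows), dtype=bool)


def acceptance_probability(motif: Motif) -> float:
    """Probability a window uniform over the 20 amino acids matches the motif."""
    p = 1.0
    for pos in motif.positions.values():
        if pos.allowed:
            ok = len(pos.allowed - pos.forbidden)
        else:
            ok = 20 - len(pos.forbidden & _AA_SET)
        p *= ok / 20.0
    return p


# ---------------------------------------------------------------------------
# Positional enrichment (consensus-logo matrices)

ENRICHMENT_POSITIONS = tuple(p for p in range(-7, 8) if p != 0)


def _column_frequencies(windows: Sequence[str]) -> pd.DataFrame:
    """Per-position residue frequencies; pads excluded per column."""
    freqs = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(ENRICHMENT_POSITIONS))
    arr = np.array([list(w) for w in windows])
    for p in ENRICHMENT_POSITIONS:
        col = arr[:, CENTER_INDEX + p]
        col = col[col != PAD]
        if col.size:
            vals, counts = np.unique(col, return_counts=True)
            s = pd.Series(counts / col.size, index=vals)
            freqs[p] = s.reindex(freqs.index).fillna(0.0)
    return freqs


def enrichment_matrix(
    foreground: Sequence[str], background: Sequence[str], pseudocount: float = 0.01
) -> pd.DataFrame:
    """log2 positional enrichment of foreground windows over background.

    ``value[a, p] = log2((f_fg(a,p) + eps) / (f_bg(a,p) + eps))`` with the
    pseudocount ``eps``; rows are the 20 amino acids, columns positions
    -7..+7 excluding 0.  Pad characters do not contribute to frequencies.
    """
    if len(foreground) == 0:
        raise ValueError("foreground window set is empty")
    if len(background) == 0:
        raise ValueError("background window set is empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for w in list(foreground) + list(background):
        if len(w) != WINDOW_LENGTH:
            raise ValueError(f"window must have length {WINDOW_LENGTH}: {w!r}")
    f_fg = _column_frequencies(foreground)
    f_bg = _column_frequencies(background)
    return np.log2((f_fg + pseudocount) / (f_bg + pseudocount))


def split_by_plus1_proline(windows: pd.DataFrame | Sequence[str]):
    """Partition sites by presence of proline at position +1.

    Accepts a DataFrame with a ``window`` column (returns two DataFrames)
    or a plain sequence of windows (returns two lists).  Stratifying on
    +1 proline separates the signature of proline-directed kinases from
    the remainder of a depleted-site logo.
    """
    if isinstance(windows, pd.DataFrame):
        mask = windows["window"].str.slice(CENTER_INDEX + 1, CENTER_INDEX + 2) == "P"
        return (
            windows.loc[mask].reset_index(drop=True),
            windows.loc[~mask].reset_index(drop=True),
        )
    with_p = [w for w in windows if w[CENTER_INDEX + 1] == "P"]
    without_p = [w for w in windows if w[CENTER_INDEX + 1] != "P"]
    return with_p, without_p


def render_logo_heatmap(matrix: pd.DataFrame, path) -> None:  # pragma: no cover
    """Cosmetic heatmap rendering of an enrichment matrix (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    vmax = float(np.abs(matrix.values).max() or 1.0)
    im = ax.imshow(matrix.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), [str(c) for c in matrix.columns])
    ax.set_yticks(range(len(matrix.index)), list(matrix.index))
    ax.set_xlabel("position relative to phosphoacceptor")
    fig.colorbar(im, ax=ax, label="log2 enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
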
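"""Kinase consensus-motif grammar, site matching, and motif statistics.

A consensus motif is written left to right in single-letter amino-acid code
with three token kinds:

* a literal residue, e.g. ``P``;
* a bracketed residue set, e.g. ``[DEN]``;
* the wildcard ``x`` (any residue).

Exactly one token carries a trailing ``*`` and marks the phospho-acceptor;
its residue set must be a subset of {S, T, Y}.  Offsets of all other tokens
are counted relative to the starred one, so ``[DEN]x[ST]*`` constrains
offset -2 to {D, E, N} and offset 0 to {S, T}.

Matching is performed against a fixed-width sequence window centred on the
phospho-acceptor.  Positions beyond the protein termini are padded with
``_``; a constrained offset that falls on padding never matches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
ACCEPTORS = frozenset("STY")

#: Consensus phosphorylation motifs for 12 kinases implicated in yeast
#: meiosis, as used for the cluster enrichment analyses.
KINASE_MOTIF_TABLE: tuple[tuple[str, str], ...] = (
    ("[LM]xx[ST]*x[STVILMFYW][YIFM]", "Atg1"),
    ("[ST]*x[RK]", "Cdc15"),
    ("[ST]*P", "Cdc28 minimal"),
    ("[ST]*Px[KR]", "Cdc28 strict"),
    ("[DEN]x[ST]*", "Cdc5"),
    ("[ST]*[DEST]", "Cdc7/Cka1"),
    ("[ST]xx[ST]*", "Hrr25"),
    ("RPx[ST]*", "Ime2"),
    ("[RK]x[ST]*", "Ipl1/PKA"),
    ("[ST]*Q", "Mec1"),
    ("[RK]xx[ST]*", "Mek1/Sgk2"),
    ("[DER]x[ST]*", "Mps1"),
)


class MotifGrammarError(ValueError):
    """Raised when a motif string does not conform to the grammar."""


@dataclass(frozen=True)
class SiteWindow:
    """Odd-length flanking-sequence window centred on the phospho-acceptor.

    ``sequence`` uses ``_`` for positions beyond the protein termini
    (MaxQuant "Sequence window" convention, default width 31 = +/-15).
    """

    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 != 1:
            raise ValueError(
                f"window length must be odd, got {len(self.sequence)}"
            )
        bad = set(self.sequence) - set(AMINO_ACIDS) - {PAD}
        if bad:
            raise ValueError(f"illegal window characters: {sorted(bad)}")

    @property
    def half_width(self) -> int:
        return len(self.sequence) // 2

    @property
    def center(self) -> str:
        return self.sequence[self.half_width]

    def residue_at(self, offset: int) -> str | None:
        """Residue at signed offset from the acceptor; None when the offset
        lies outside the window or on terminal padding."""
        i = self.half_width + offset
        if not 0 <= i < len(self.sequence):
            return None
        ch = self.sequence[i]
        return None if ch == PAD else ch


@dataclass(frozen=True)
class MotifPattern:
    """Parsed consensus motif: offset -> allowed residue set, 0 = acceptor."""

    name: str
    pattern_text: str
    constraints: Mapping[int, frozenset[str]] = field(hash=False)

    def __post_init__(self) -> None:
        if 0 not in self.constraints:
            raise ValueError("motif must constrain offset 0 (the acceptor)")
        if not set(self.constraints[0]) <= ACCEPTORS:
            raise ValueError("acceptor set must be a subset of {S,T,Y}")
        for off, residues in self.constraints.items():
            if not residues:
                raise ValueError(f"empty residue set at offset {off}")

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(sorted(self.constraints))


def _tokenize(pattern_text: str) -> list[tuple[frozenset[str] | None, bool]]:
    """Split a motif string into (residue set or None for wildcard, starred)."""
    tokens: list[tuple[frozenset[str] | None, bool]] = []
    i = 0
    while i < len(pattern_text):
        ch = pattern_text[i]
        if ch == "[":
            j = pattern_text.find("]", i)
            if j < 0:
                raise MotifGrammarError(
                    f"unclosed bracket at position {i} in {pattern_text!r}"
                )
            residues = pattern_text[i + 1 : j]
            if not residues:
                raise MotifGrammarError(f"empty bracket in {pattern_text!r}")
            bad = set(residues) - set(AMINO_ACIDS)
            if bad:
                raise MotifGrammarError(
                    f"illegal residue {sorted(bad)} in {pattern_text!r}"
                )
            tok: frozenset[str] | None = frozenset(residues)
            i = j + 1
        elif ch == "x":
            tok = None
            i += 1
        elif ch in AMINO_ACIDS:
            tok = frozenset(ch)
            i += 1
        else:
            raise MotifGrammarError(
                f"illegal character {ch!r} at position {i} in {pattern_text!r}"
            )
        starred = i < len(pattern_text) and pattern_text[i] == "*"
        if starred:
            i += 1
        tokens.append((tok, starred))
    return tokens


def parse_motif(pattern_text: str, name: str = "") -> MotifPattern:
    """Parse a motif string into positional residue-set constraints.

    >>> parse_motif("[DEN]x[ST]*").constraints[-2] == frozenset("DEN")
    True
    """
    tokens = _tokenize(pattern_text)
    star_indices = [k for k, (_, starred) in enumerate(tokens) if starred]
    if len(star_indices) != 1:
        raise MotifGrammarError(
            f"exactly one starred acceptor token required, "
            f"found {len(star_indices)} in {pattern_text!r}"
        )
    star = star_indices[0]
    if tokens[star][0] is None:
        raise MotifGrammarError(
            f"the starred token may not be the wildcard in {pattern_text!r}"
        )
    constraints: dict[int, frozenset[str]] = {}
    for k, (tok, _) in enumerate(tokens):
        if tok is not None:
            constraints[k - star] = tok
    return MotifPattern(
        name=name or pattern_text,
        pattern_text=pattern_text,
        constraints=constraints,
    )


def builtin_kinase_motifs() -> list[MotifPattern]:
    """The packaged 12-kinase consensus motif set."""
    return [parse_motif(p, name) for p, name in KINASE_MOTIF_TABLE]


def match_site(window: SiteWindow, pattern: MotifPattern) -> bool:
    """True iff every constrained offset of the motif is satisfied.

    Padding (or an offset outside the window) at a constrained position
    fails the match; the function is total and never raises.
    """
    for off, residues in pattern.constraints.items():
        residue = window.residue_at(off)
        if residue is None or residue not in residues:
            return False
    return True


def match_table(
    windows: Mapping[str, SiteWindow] | pd.Series,
    patterns: Sequence[MotifPattern],
) -> pd.DataFrame:
    """Boolean site x motif match matrix (deterministic in inputs)."""
    if isinstance(windows, pd.Series):
        items = list(windows.items())
    else:
        items = list(windows.items())
    idx = [k for k, _ in items]
    data = {
        p.name: [match_site(w, p) for _, w in items] for p in patterns
    }
    return pd.DataFrame(data, index=pd.Index(idx, name="site"))


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cutoff, stars in STAR_LEVELS:
        if p < cutoff:
            return stars
    return ""


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns (odds ratio, p).  The odds ratio is the sample ad/bc with the
    usual infinity convention.
    """
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def fisher_family_pvalues(n_total: int, row1: int, col1: int) -> np.ndarray:
    """Two-sided Fisher p for every table sharing the given margins.

    For fixed margins (row1, n_total - row1) x (col1, n_total - col1) the
    table is determined by its top-left count a; this returns the
    two-sided p for each a in the support, computed by summing all
    point probabilities not exceeding the observed one (with the
    customary 1 + 1e-7 relative tie tolerance).  Vectorizing over the
    whole margin family makes exhaustive verification over all small
    tables feasible; the values agree with the per-table
    :func:`fisher_test` to machine precision.
    """
    a_min = max(0, row1 + col1 - n_total)
    a_max = min(row1, col1)
    ks = np.arange(a_min, a_max + 1)
    pmf = stats.hypergeom.pmf(ks, n_total, row1, col1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cumsum = np.cumsum(sorted_pmf)
    pos = np.searchsorted(sorted_pmf, pmf * (1.0 + 1e-7), side="right")
    p = np.where(pos > 0, cumsum[np.clip(pos - 1, 0, None)], 0.0)
    return np.minimum(p, 1.0)


def motif_enrichment(
    groups: Mapping[str, Sequence[str]],
    background: Sequence[str],
    matches: pd.DataFrame,
    mode: str = "total",
) -> pd.DataFrame:
    """Per (group, motif) Fisher enrichment of motif matches.

    ``matches`` is a site x motif boolean table covering every site id in
    the groups and the background.  Two table constructions are offered:

    * ``"total"`` (default): the group is compared against the whole
      background *including* the group itself, i.e. selected cluster vs
      all clusters.  The rows of this 2x2 table are not disjoint; this
      construction is kept for fidelity with the published barplots but
      is statistically non-standard — interpret p-values with care.
    * ``"rest"``: the group is compared against background minus group
      (disjoint rows; the textbook construction).
    """
    if mode not in ("total", "rest"):
        raise ValueError(f"unknown mode {mode!r}")
    bg = pd.Index(background)
    rows = []
    for label, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"empty group {label!r}")
        member_idx = pd.Index(members)
        if not member_idx.isin(matches.index).all():
            missing = member_idx[~member_idx.isin(matches.index)]
            raise KeyError(f"group {label!r} sites absent from match table: "
                           f"{list(missing[:5])}")
        other = bg if mode == "total" else bg.difference(member_idx)
        for motif in matches.columns:
            col = matches[motif]
            a = int(col.loc[member_idx].sum())
            b = len(member_idx) - a
            c = int(col.loc[other].sum())
            d = len(other) - c
            odds, p = fisher_test(a, b, c, d)
            frac_g = a / (a + b)
            frac_bg = c / (c + d) if (c + d) else float("nan")
            rows.append(
                {
                    "group": label,
                    "motif": motif,
                    "n_group_match": a,
                    "n_group_nonmatch": b,
                    "n_bg_match": c,
                    "n_bg_nonmatch": d,
                    "pct_group": 100.0 * frac_g,
                    "pct_bg": 100.0 * frac_bg,
                    "odds_ratio": odds,
                    "p_value": p,
                    "direction": "enriched" if frac_g >= frac_bg else "depleted",
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def _offset_residue_counts(
    windows: Sequence[SiteWindow], offsets: Sequence[int]
) -> dict[int, dict[str, int]]:
    counts: dict[int, dict[str, int]] = {o: {} for o in offsets}
    for w in windows:
        for o in offsets:
            r = w.residue_at(o)
            if r is not None:
                counts[o][r] = counts[o].get(r, 0) + 1
    return counts


def residue_logo(
    fg: Sequence[SiteWindow],
    bg: Sequence[SiteWindow],
    alpha: float = 0.05,
    include_center: bool = False,
) -> pd.DataFrame:
    """Percent-difference residue logo with per-cell Fisher significance.

    For every (offset, residue) the percentage of foreground windows
    carrying that residue at that offset is compared against the
    background percentage; the difference is tested with a two-sided
    Fisher exact test on the underlying counts.  Padding positions are
    excluded from the per-offset denominators.  Offset 0 is excluded by
    default because it is conditioned on the acceptor alphabet.
    """
    if not fg or not bg:
        raise ValueError("foreground and background must be nonempty")
    widths = {len(w.sequence) for w in itertools.chain(fg, bg)}
    if len(widths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(widths)}")
    half = widths.pop() // 2
    offsets = [o for o in range(-half, half + 1) if include_center or o != 0]
    fg_counts = _offset_residue_counts(fg, offsets)
    bg_counts = _offset_residue_counts(bg, offsets)
    rows = []
    for o in offsets:
        n_fg = sum(fg_counts[o].values())
        n_bg = sum(bg_counts[o].values())
        if n_fg == 0 or n_bg == 0:
            continue
        for residue in AMINO_ACIDS:
            a = fg_counts[o].get(residue, 0)
            c = bg_counts[o].get(residue, 0)
            if a == 0 and c == 0:
                continue
            fg_pct = 100.0 * a / n_fg
            bg_pct = 100.0 * c / n_bg
            _, p = fisher_test(a, n_fg - a, c, n_bg - c)
            rows.append(
                {
                    "offset": o,
                    "residue": residue,
                    "fg_pct": fg_pct,
                    "bg_pct": bg_pct,
                    "pct_difference": fg_pct - bg_pct,
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def discover_submotif(
    base: MotifPattern,
    offset: int,
    fg: Sequence[SiteWindow],
    bg: Sequence[SiteWindow],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-offset refinement of a consensus motif.

    Among windows matching ``base`` the residue distribution at an
    unconstrained ``offset`` is compared between a foreground set (e.g.
    sites losing phosphorylation in a mutant) and a background set; each
    residue is tested by a two-sided Fisher exact test.  Returns the
    residues enriched in the foreground with p < alpha, ranked by p
    (best first), with counts and percentages.
    """
    if offset in base.constraints:
        raise ValueError(
            f"offset {offset} is already constrained in {base.pattern_text!r}"
        )
    fg_m = [w for w in fg if match_site(w, base)]
    bg_m = [w for w in bg if match_site(w, base)]
    if not fg_m or not bg_m:
        raise ValueError("no base-motif-matching windows in fg or bg")
    fg_counts = _offset_residue_counts(fg_m, [offset])[offset]
    bg_counts = _offset_residue_counts(bg_m, [offset])[offset]
    n_fg = sum(fg_counts.values())
    n_bg = sum(bg_counts.values())
    rows = []
    for residue in AMINO_ACIDS:
        a = fg_counts.get(residue, 0)
        c = bg_counts.get(residue, 0)
        if a == 0 and c == 0:
            continue
        odds, p = fisher_test(a, n_fg - a, c, n_bg - c)
        enriched = (a / n_fg) > (c / n_bg if n_bg else 0.0)
        if p < alpha and enriched:
            rows.append(
                {
                    "residue": residue,
                    "offset": offset,
                    "n_fg": a,
                    "n_fg_total": n_fg,
                    "n_bg": c,
                    "n_bg_total": n_bg,
                    "fg_pct": 100.0 * a / n_fg,
                    "bg_pct": 100.0 * c / n_bg,
                    "odds_ratio": odds,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "residue", "offset", "n_fg", "n_fg_total", "n_bg", "n_bg_total",
            "fg_pct", "bg_pct", "odds_ratio", "p_value",
        ],
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def scan_protein_sequence(
    sequence: str, pattern_text: str = "S[ST]P"
) -> list[int]:
    """All (overlapping) 1-based start positions of a plain positional motif.

    The pattern uses the same token alphabet as consensus motifs but has no
    starred acceptor; a star is rejected as the wrong grammar.
    """
    if "*" in pattern_text:
        raise MotifGrammarError(
            "positional scan patterns must not contain a star"
        )
    tokens = [tok for tok, _ in _tokenize(pattern_text)]
    seq = sequence.upper()
    span = len(tokens)
    hits = []
    for start in range(len(seq) - span + 1):
        ok = True
        for j, tok in enumerate(tokens):
            ch = seq[start + j]
            if tok is not None and ch not in tok:
                ok = False
                break
        if ok:
            hits.append(start + 1)
    return hits
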
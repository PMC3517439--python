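"""Per-family statistics for transposable-element copies.

This module carries the quantitative core of the analysis:

* majority-rule consensus reconstruction from aligned copies, which
  approximates the ancestral active element;
* the Kimura two-parameter (K80) distance, separating transitions
  (A<->G, C<->T; proportion ``P``) from transversions (proportion ``Q``):

  .. math:: d = -\\tfrac12 \\ln(1 - 2P - Q) - \\tfrac14 \\ln(1 - 2Q)

* family divergence — the mean K2P distance of individual insertions to
  the family consensus, a proxy for the time since the amplification
  burst;
* percent identity between consensus sequences (the cross-genome
  similarity that flags horizontal transfer);
* a reduced seed-and-extend homology search used to count family copies
  in a genome sequence.

Columns containing N are never counted in distances or identities, and N
never wins a consensus column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import numpy as np
from Bio import Align

from .core_io import Alignment, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "K2PResult",
    "TEFamilyObservation",
    "IdentityMatrix",
    "SaturatedDistanceError",
    "NoComparableSitesError",
    "build_consensus",
    "k2p_distance",
    "k2p_counts",
    "family_divergence",
    "pairwise_identity",
    "global_align",
    "find_copies",
    "Hit",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturatedDistanceError(ValueError):
    """The K2P log arguments are non-positive; the distance is undefined."""


class NoComparableSitesError(ValueError):
    """No alignment column has an unambiguous base in both sequences."""


class K2PResult(NamedTuple):
    d: float        # substitutions/site
    P: float        # transition proportion
    Q: float        # transversion proportion
    sites: int      # comparable sites used


@dataclass
class TEFamilyObservation:
    """One TE family observed in one genome (a divergence-table row)."""

    family: str
    genome: str
    consensus: Sequence
    copy_number: int
    divergence_mean: float   # percent substitutions/site
    divergence_sd: float     # percent
    n_sampled: int

    def __post_init__(self) -> None:
        if self.divergence_mean < 0:
            raise ValueError("divergence_mean must be >= 0")
        if "-" in self.consensus.residues:
            raise ValueError("consensus must be gap-free")
        if self.n_sampled > self.copy_number:
            raise ValueError("n_sampled cannot exceed copy_number")

    @property
    def consensus_length(self) -> int:
        return len(self.consensus.residues)

    def divergence_cell(self) -> str:
        """Report-style cell, e.g. ``15.0 ± 2 (183)``."""
        return f"{self.divergence_mean:.1f} ± {round(self.divergence_sd):d} ({self.n_sampled})"


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity table between labelled consensuses."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("identity matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("identities must lie in [0, 100]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.values[self.labels.index(pair[0]), self.labels.index(pair[1])])


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def build_consensus(aln: Alignment, gap_threshold: float = 0.5) -> Sequence:
    """Majority-rule consensus of aligned copies.

    Per column: if the gap fraction exceeds ``gap_threshold`` the column
    is dropped; otherwise the consensus residue is the most frequent
    base among {A, C, G, T}, ties broken in the fixed order A < C < G < T.
    Columns with no countable base (all gaps/N) are dropped too. The
    result is gap-free.

    Raises ``ValueError("no consensus columns")`` if every column drops.
    """
    arr = aln.as_array()
    n = arr.shape[0]
    out: list[str] = []
    # counts per base per column, vectorized over columns
    gap_frac = (arr == b"-").sum(axis=0) / n
    base_counts = np.stack([(arr == base.encode()).sum(axis=0) for base in "ACGT"])
    for col in range(arr.shape[1]):
        if gap_frac[col] > gap_threshold:
            continue
        counts = base_counts[:, col]
        if counts.sum() == 0:
            continue  # only gaps and Ns survive the gap filter
        out.append("ACGT"[int(np.argmax(counts))])  # argmax takes first max: A<C<G<T
    if not out:
        raise ValueError("no consensus columns")
    return Sequence(f"{aln.members[0].id}_consensus" if aln.members else "consensus", "".join(out))


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

def k2p_counts(a: Sequence, b: Sequence) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) between aligned sequences.

    Only columns where both residues are in {A, C, G, T} are compared.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError("sequences must be aligned to equal length")
    x = a.as_array()
    y = b.as_array()
    bases = np.array([b"A", b"C", b"G", b"T"])
    ok = np.isin(x, bases) & np.isin(y, bases)
    xs, ys = x[ok], y[ok]
    diff = xs != ys
    purine_x = (xs == b"A") | (xs == b"G")
    purine_y = (ys == b"A") | (ys == b"G")
    transitions = int((diff & (purine_x == purine_y)).sum())
    transversions = int((diff & (purine_x != purine_y)).sum())
    return transitions, transversions, int(ok.sum())


def k2p_distance(a: Sequence, b: Sequence) -> K2PResult:
    """Kimura two-parameter distance between two aligned sequences.

    Returns ``(d, P, Q, sites)`` with ``d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)``.
    Raises :class:`NoComparableSitesError` when no column is comparable and
    :class:`SaturatedDistanceError` when a log argument is non-positive.
    """
    ts, tv, sites = k2p_counts(a, b)
    if sites == 0:
        raise NoComparableSitesError("no comparable sites")
    P = ts / sites
    Q = tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError("saturated")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d=d, P=P, Q=Q, sites=sites)


# ---------------------------------------------------------------------------
# Family divergence
# ---------------------------------------------------------------------------

def family_divergence(
    copies: Iterable[Sequence],
    consensus: Sequence,
    min_coverage: float = 0.7,
    sample_size: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float, int]:
    """Mean/SD (in %) of per-copy K2P distances to the family consensus.

    ``copies`` must be aligned to ``consensus`` (same gapped length).
    Copies whose comparable sites fall below ``min_coverage`` times the
    ungapped consensus length are excluded, mirroring the usual practice
    of only scoring insertions that match most of the consensus. If
    ``sample_size`` is given, that many copies are drawn without
    replacement before filtering. Saturated copies are excluded with a
    warning. Returns ``(mean_pct, sd_pct, n_used)``; SD is the sample
    standard deviation (0.0 when a single copy qualifies).
    """
    copies = list(copies)
    if sample_size is not None and sample_size < len(copies):
        if rng is None:
            raise ValueError("sampling requires an rng")
        idx = rng.choice(len(copies), size=sample_size, replace=False)
        copies = [copies[i] for i in sorted(idx)]
    ref_len = consensus.ungapped_length
    dists: list[float] = []
    for c in copies:
        try:
            res = k2p_distance(c, consensus)
        except NoComparableSitesError:
            continue
        except SaturatedDistanceError:
            logger.warning("copy %s saturated against consensus; excluded", c.id)
            continue
        if res.sites < min_coverage * ref_len:
            continue
        dists.append(res.d)
    if not dists:
        raise ValueError("no qualifying copies for family divergence")
    arr = np.array(dists) * 100.0
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

def global_align(a: Sequence, b: Sequence) -> tuple[str, str]:
    """Needleman-Wunsch global alignment (match 1, mismatch -1, gap -2).

    Returns the two gapped strings. Deterministic: the aligner's first
    optimal alignment is used.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alns = aligner.align(a.residues.replace("-", ""), b.residues.replace("-", ""))
    best = alns[0]
    return str(best[0]), str(best[1])


def pairwise_identity(
    a: Sequence,
    b: Sequence,
    prealigned: bool = False,
    mode: str = "gap-mismatch",
) -> float:
    """Percent identity between two consensus sequences.

    ``mode='gap-mismatch'`` (default): the denominator is every column
    where at least one residue is a base; gap-vs-base counts as mismatch
    and gap-vs-gap columns are ignored. ``mode='gap-exclude'``: columns
    containing any gap are ignored entirely. Columns containing N are
    excluded under both conventions. Unaligned inputs are first globally
    aligned with :func:`global_align`.
    """
    if mode not in ("gap-mismatch", "gap-exclude"):
        raise ValueError(f"unknown identity mode: {mode}")
    if prealigned:
        if len(a.residues) != len(b.residues):
            raise ValueError("prealigned sequences must have equal length")
        sa, sb = a.residues, b.residues
    else:
        sa, sb = global_align(a, b)
    matches = 0
    denom = 0
    for x, y in zip(sa, sb):
        if x == "N" or y == "N":
            continue
        x_base = x in "ACGT"
        y_base = y in "ACGT"
        if not x_base and not y_base:
            continue  # gap vs gap
        if mode == "gap-exclude" and (not x_base or not y_base):
            continue
        denom += 1
        if x == y:
            matches += 1
    if denom == 0:
        raise ValueError("empty overlap between sequences")
    return 100.0 * matches / denom


def identity_matrix(
    labelled: list[tuple[str, Sequence]],
    prealigned: bool = False,
    mode: str = "gap-mismatch",
) -> IdentityMatrix:
    """Square percent-identity matrix between labelled consensuses."""
    n = len(labelled)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(labelled[i][1], labelled[j][1], prealigned=prealigned, mode=mode)
            vals[i, j] = vals[j, i] = pid
    return IdentityMatrix([lab for lab, _ in labelled], vals)


# ---------------------------------------------------------------------------
# Copy discovery (reduced seed-and-extend homology search)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


class Hit(NamedTuple):
    start: int        # genome coordinate, 0-based inclusive
    end: int          # genome coordinate, exclusive
    strand: str       # '+' or '-'
    identity: float   # matches / aligned length
    coverage: float   # aligned query span / query length


def _extend(genome: str, query: str, g0: int, q0: int, word: int, xdrop: int) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of an exact seed on one diagonal.

    Scoring: match +1, mismatch -2; extension stops when the running
    score falls ``xdrop`` below the best seen. Returns
    (g_start, g_end, q_start, q_end, matches) of the best-scoring span.
    """
    # right extension
    score = word
    best = score
    g, q = g0 + word, q0 + word
    best_g_end, best_q_end = g, q
    matches_right = 0
    best_matches_right = 0
    while g < len(genome) and q < len(query):
        if genome[g] == query[q] and genome[g] in "ACGT":
            score += 1
            matches_right += 1
        else:
            score -= 2
        g += 1
        q += 1
        if score > best:
            best, best_g_end, best_q_end, best_matches_right = score, g, q, matches_right
        elif best - score > xdrop:
            break
    # left extension
    score = best
    best2 = score
    g, q = g0, q0
    best_g_start, best_q_start = g, q
    matches_left = 0
    best_matches_left = 0
    while g > 0 and q > 0:
        g -= 1
        q -= 1
        if genome[g] == query[q] and genome[g] in "ACGT":
            score += 1
            matches_left += 1
        else:
            score -= 2
        if score > best2:
            best2, best_g_start, best_q_start, best_matches_left = score, g, q, matches_left
        elif best2 - score > xdrop:
            break
    matches = word + best_matches_right + best_matches_left
    return best_g_start, best_g_end, best_q_start, best_q_end, matches


def find_copies(
    genome: Sequence,
    query: Sequence,
    word_size: int = 11,
    min_identity: float = 0.6,
    min_length: int = 100,
    xdrop: int = 20,
) -> list[Hit]:
    """Count family copies in a genome with a reduced BLASTN-like search.

    Exact ``word_size``-mers of the query are matched on both strands and
    extended ungapped with an X-drop rule (match +1, mismatch -2, drop
    20). Overlapping hits on the same strand are merged keeping the
    higher-identity span; hits shorter than ``min_length`` or below
    ``min_identity`` are discarded. This is an intentionally simplified
    surrogate for a full gapped search: copy counts on real genomes will
    undercount diverged, indel-rich copies.
    """
    g = genome.residues.replace("-", "")
    raw_hits: list[Hit] = []
    for strand in "+-":
        q = query.residues.replace("-", "") if strand == "+" else _revcomp(query.residues.replace("-", ""))
        if len(q) < word_size:
            continue
        index: dict[str, list[int]] = {}
        for i in range(len(q) - word_size + 1):
            w = q[i : i + word_size]
            if "N" in w:
                continue
            index.setdefault(w, []).append(i)
        seen_diag_spans: dict[int, list[tuple[int, int]]] = {}
        for gpos in range(len(g) - word_size + 1):
            w = g[gpos : gpos + word_size]
            hits = index.get(w)
            if not hits:
                continue
            for qpos in hits:
                diag = gpos - qpos
                spans = seen_diag_spans.get(diag, [])
                if any(s <= gpos < e for s, e in spans):
                    continue  # seed already inside an extension on this diagonal
                gs, ge, qs, qe, matches = _extend(g, q, gpos, qpos, word_size, xdrop)
                seen_diag_spans.setdefault(diag, []).append((gs, ge))
                length = ge - gs
                if length < min_length:
                    continue
                ident = matches / length
                if ident < min_identity:
                    continue
                raw_hits.append(Hit(gs, ge, strand, ident, (qe - qs) / len(q)))
    # merge overlapping hits per strand, keeping the better span
    merged: list[Hit] = []
    for strand in "+-":
        strand_hits = sorted((h for h in raw_hits if h.strand == strand), key=lambda h: (h.start, -(h.end - h.start)))
        for h in strand_hits:
            if merged and merged[-1].strand == strand and h.start < merged[-1].end:
                keep = max(merged[-1], h, key=lambda x: (x.identity * (x.end - x.start)))
                merged[-1] = keep
            else:
                merged.append(h)
    merged.sort(key=lambda h: h.start)
    return merged
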
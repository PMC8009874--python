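"""Capture probe design: tiling, filtering, scoring and windowed selection.

The design procedure, run per consolidated target region:

1. Tile variable-length candidate probes (50–100 bases by default) at a
   five-base step, allowing starts up to ``flank_allowance`` bases before
   the target and ends the same distance past it.
2. Flag *repetitive* candidates: mean genome-wide 15-mer occurrence count
   over the probe's sliding 15-base windows above ``repetitive_threshold``
   (default 100).  Repetitive candidates are removed before uniqueness
   scoring.
3. Flag *non-unique* candidates: more than ``max_close_matches`` (default
   5) genome loci, on either strand, where some 30-base stretch of the
   probe aligns with at most 5 edits.  The probe's own origin locus counts.
4. Score the remaining candidates by a weighted sum of repetitiveness,
   close-match excess, melting-temperature deviation from a target, and a
   sequence-composition penalty (lower is better).
5. Slide a 20-base selection window from ``target.start − flank`` in
   40-base steps; in each window pick the best-scoring eligible candidate
   (ties: leftmost start, then shortest).

Hybridization is strand-symmetric, so k-mers are counted in canonical
(lexicographically minimal of forward/reverse-complement) form and
close matches are searched on both strands.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from exomekit.reference_io import (
    Feature,
    GenomeSequence,
    RegionSet,
    TargetRegion,
    consolidate_targets,
    write_bed,
)

log = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class DesignParameters:
    """All tunable design constants.

    Defaults follow the published capture-design description where one is
    given (probe lengths 50–100, five-base tiling, k = 15 with repetitive
    cutoff 100, 30-base close matches with ≤ 5 edits and at most 5 genome
    placements, 20-base selection windows advanced 40 bases, ±30-base flank
    allowance).  Quantities the description leaves open (Tm model and
    target, composition metric, score weights, indirect-coverage reach)
    have documented defaults here.
    """

    k: int = 15
    repetitive_threshold: float = 100.0
    close_match_len: int = 30
    close_match_max_edits: int = 5
    max_close_matches: int = 5
    close_match_seed_len: int = 5  # pigeonhole-safe for <=5 edits over 30 bases
    count_origin_locus: bool = True
    probe_len_min: int = 50
    probe_len_max: int = 100
    probe_len_step: int = 10
    tile_step: int = 5
    window_len: int = 20
    window_advance: int = 40
    probes_per_window: int = 4
    flank_allowance: int = 30
    tm_target: float = 72.0  # deg C; mid-range for 50-100-mers at defaults below
    tm_salt_mM: float = 50.0
    tm_dnac_nM: float = 0.25  # 250 pM
    score_weights: tuple = (1.0, 1.0, 0.2, 1.0)  # (repetitiveness, uniqueness, Tm, composition)
    comp_gc_weight: float = 1.0
    comp_homopolymer_weight: float = 0.1
    canonical_kmers: bool = True
    indirect_reach: int = 100

    def __post_init__(self):
        if self.probe_len_min > self.probe_len_max:
            raise ValueError("probe_len_min must be <= probe_len_max")
        if not 1 <= self.probes_per_window <= 4:
            raise ValueError("probes_per_window must be in [1, 4]")
        for name in ("k", "close_match_len", "probe_len_min", "probe_len_max",
                     "probe_len_step", "tile_step", "window_len", "window_advance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.score_weights) != 4:
            raise ValueError("score_weights must have four components")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "DesignParameters":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValueError(f"unknown design parameters: {sorted(unknown)}")
        if "score_weights" in known:
            known["score_weights"] = tuple(known["score_weights"])
        return cls(**known)


def _sequences(genome) -> dict[str, str]:
    """Accept either {name: GenomeSequence} or {name: str}."""
    out = {}
    for name, val in genome.items():
        out[name] = val.sequence if isinstance(val, GenomeSequence) else str(val)
    return out


# --- k-mer repetitiveness ----------------------------------------------------


@dataclass
class KmerIndex:
    """Genome-wide k-mer occurrence counts (canonical form by default)."""

    k: int
    counts: Counter
    canonical: bool = True

    def count(self, kmer: str) -> int:
        if "N" in kmer:
            return 0
        key = canonical_kmer(kmer) if self.canonical else kmer
        return self.counts.get(key, 0)


def build_kmer_index(genome, k: int = 15, canonical: bool = True) -> KmerIndex:
    """Count every N-free k-mer across the whole genome.

    The total of all stored counts equals the number of valid k-mer
    positions; k-mers containing N are never stored.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = _sequences(genome)
    if not seqs:
        raise ValueError("genome is empty")
    counts: Counter = Counter()
    any_window = False
    for seq in seqs.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            any_window = True
            counts[canonical_kmer(kmer) if canonical else kmer] += 1
    if not any_window:
        log.warning("k=%d produced no valid k-mer windows; index is empty", k)
    return KmerIndex(k=k, counts=counts, canonical=canonical)


def probe_repetitiveness(probe_sequence: str, index: KmerIndex) -> float:
    """Mean index count over the probe's (L − k + 1) sliding k-mer windows.

    Windows absent from the index (e.g. containing N) contribute 0.
    """
    k = index.k
    if len(probe_sequence) < k:
        raise ValueError(f"probe length {len(probe_sequence)} shorter than k={k}")
    n = len(probe_sequence) - k + 1
    total = sum(index.count(probe_sequence[i : i + k]) for i in range(n))
    return total / n


# --- close-match uniqueness --------------------------------------------------


def _infix_hit_ends(pattern: str, text: str, max_edits: int) -> list[int]:
    """All end positions e in ``text`` where some substring ending at e
    matches ``pattern`` with edit distance <= max_edits (free start).

    Classic semi-global DP, one row per pattern character; the
    within-row dependency dp[j] = min(dp[j], dp[j-1] + 1) is resolved with
    a running-minimum pass, keeping the recurrence exact.
    """
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)
    cur = [0] * (n + 1)
    for i in range(1, m + 1):
        pc = pattern[i - 1]
        cur[0] = i
        best = cur[0]
        for j in range(1, n + 1):
            cost = 0 if text[j - 1] == pc else 1
            v = prev[j - 1] + cost
            up = prev[j] + 1
            if up < v:
                v = up
            left = best + 1
            if left < v:
                v = left
            cur[j] = v
            best = v
        prev, cur = cur, prev
    return [j - 1 for j in range(1, n + 1) if prev[j] <= max_edits]


def merge_hit_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping (not merely book-ended) intervals into loci."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


class CloseMatchSearcher:
    """Seed-and-verify search for ~30-base close matches across a genome.

    A close match is a genome locus, on either strand, where some
    ``close_match_len``-base window of the probe aligns with at most
    ``close_match_max_edits`` edits.  With 6 non-overlapping seeds of
    length 5 over a 30-base window, any alignment with <= 5 edits must
    contain one exact seed (pigeonhole), so seeded search finds exactly
    the hits a full scan would.  Candidate regions are pre-screened with
    edlib before the exact semi-global DP enumerates qualifying alignment
    end positions; hits whose genome intervals overlap on the same strand
    are merged into a single locus.
    """

    def __init__(self, genome, params: DesignParameters | None = None):
        self.params = params or DesignParameters()
        self.seqs = _sequences(genome)
        p = self.params
        if p.close_match_seed_len * (p.close_match_max_edits + 1) > p.close_match_len:
            raise ValueError(
                "seed length too large: pigeonhole guarantee requires "
                "seed_len * (max_edits + 1) <= close_match_len"
            )
        self._seed_index: dict[str, dict[str, np.ndarray]] = {}
        s = p.close_match_seed_len
        for chrom, seq in self.seqs.items():
            idx: dict[str, list[int]] = {}
            for i in range(len(seq) - s + 1):
                seed = seq[i : i + s]
                if "N" in seed:
                    continue
                idx.setdefault(seed, []).append(i)
            self._seed_index[chrom] = {k: np.asarray(v) for k, v in idx.items()}
        # window-level hit cache: overlapping candidates share windows
        self._window_hits = lru_cache(maxsize=500_000)(self._window_hits_uncached)

    def _window_hits_uncached(self, window: str) -> tuple:
        """Qualifying alignment end positions of one pattern over every
        chromosome's forward text: tuple of (chrom, ends-tuple)."""
        p = self.params
        w, e = p.close_match_len, p.close_match_max_edits
        s = p.close_match_seed_len
        n_seeds = w // s
        out = []
        for chrom, seq in self.seqs.items():
            index = self._seed_index[chrom]
            anchors: list[np.ndarray] = []
            for t in range(n_seeds):
                seed = window[t * s : (t + 1) * s]
                pos = index.get(seed)
                if pos is not None:
                    anchors.append(pos - t * s)
            if not anchors:
                continue
            # candidate regions around each anchor; merge before verifying
            aa = np.unique(np.concatenate(anchors))
            regions = merge_hit_intervals(
                (max(0, int(a) - w // 2), min(len(seq), int(a) + w + 10)) for a in aa
            )
            ends: set[int] = set()
            for b, e2 in regions:
                chunk = seq[b:e2]
                # fast reject: no alignment with <= e edits anywhere in chunk
                if edlib.align(window, chunk, mode="HW", task="distance", k=e)[
                    "editDistance"
                ] == -1:
                    continue
                for rel_end in _infix_hit_ends(window, chunk, e):
                    ends.add(b + rel_end + 1)  # absolute exclusive end
            if ends:
                out.append((chrom, tuple(sorted(ends))))
        return tuple(out)

    def count(self, sequence: str) -> int:
        """Number of distinct close-match loci for a probe, both strands."""
        p = self.params
        w = p.close_match_len
        if len(sequence) < w:
            raise ValueError(f"probe shorter than close_match_len={w}")
        # ends[(chrom, strand)] -> set of alignment end positions
        ends: dict[tuple[str, str], set[int]] = {}
        for j in range(len(sequence) - w + 1):
            win = sequence[j : j + w]
            if "N" in win:
                continue
            for strand, pattern in (("+", win), ("-", reverse_complement(win))):
                for chrom, hit_ends in self._window_hits(pattern):
                    ends.setdefault((chrom, strand), set()).update(hit_ends)
        n_loci = 0
        for hit_ends in ends.values():
            intervals = [(max(0, e - w), e) for e in sorted(hit_ends)]
            n_loci += len(merge_hit_intervals(intervals))
        return n_loci


def count_close_matches(
    sequence: str,
    genome,
    params: DesignParameters | None = None,
    searcher: CloseMatchSearcher | None = None,
) -> int:
    """Count distinct genome loci (either strand) with a <= max-edit match
    to some ``close_match_len`` stretch of the probe; the probe's origin
    locus is included."""
    if searcher is None:
        searcher = CloseMatchSearcher(genome, params)
    return searcher.count(sequence)


# --- per-probe scores --------------------------------------------------------


def melting_temperature(sequence: str, params: DesignParameters | None = None) -> float:
    """Duplex melting temperature (deg C) from nearest-neighbor
    thermodynamics (unified parameter set) at the configured monovalent
    salt and strand concentration."""
    p = params or DesignParameters()
    if not sequence:
        raise ValueError("empty sequence")
    if set(sequence) - set("ACGT"):
        raise ValueError("melting_temperature requires a sequence over {A,C,G,T}")
    return float(
        _mt.Tm_NN(sequence, Na=p.tm_salt_mM, dnac1=p.tm_dnac_nM, dnac2=0)
    )


def longest_homopolymer(sequence: str) -> int:
    best = run = 0
    prev = None
    for c in sequence:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def composition_penalty(sequence: str, params: DesignParameters | None = None) -> float:
    """GC-deviation plus homopolymer-excess penalty (>= 0, strand-symmetric):
    w_gc * |GC − 0.5| + w_homo * max(0, longest_homopolymer − 5)."""
    p = params or DesignParameters()
    gc = sum(1 for c in sequence if c in "GC") / len(sequence)
    return p.comp_gc_weight * abs(gc - 0.5) + p.comp_homopolymer_weight * max(
        0, longest_homopolymer(sequence) - 5
    )


@dataclass
class CandidateProbe:
    chrom: str
    start: int
    length: int
    sequence: str
    repetitiveness: float | None = None
    close_matches: int | None = None
    tm: float | None = None
    composition_penalty: float | None = None
    score: float | None = None
    repetitive: bool = False
    nonunique: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def passed(self) -> bool:
        return (
            self.repetitiveness is not None
            and not self.repetitive
            and not self.nonunique
        )


def score_probe(c: CandidateProbe, params: DesignParameters) -> float:
    """Combined probe score (lower is better):
    w_rep*log10(1+rep) + w_uni*max(0, close_matches−1) + w_tm*|Tm−target| + w_comp*penalty.
    """
    if None in (c.repetitiveness, c.close_matches, c.tm, c.composition_penalty):
        raise ValueError("candidate has unpopulated score components")
    w_rep, w_uni, w_tm, w_comp = params.score_weights
    return (
        w_rep * math.log10(1.0 + c.repetitiveness)
        + w_uni * max(0, c.close_matches - 1)
        + w_tm * abs(c.tm - params.tm_target)
        + w_comp * c.composition_penalty
    )


# --- tiling and selection ----------------------------------------------------


def tile_candidates(
    target: TargetRegion, genome, params: DesignParameters | None = None
) -> list[CandidateProbe]:
    """Enumerate candidate probes across a target plus its flank allowance.

    Starts run from ``target.start − flank_allowance`` at ``tile_step``
    increments; for each start, one candidate per allowed length whose end
    stays within ``target.end + flank_allowance``.  Candidates containing
    N are dropped; candidates must also lie within the chromosome.
    """
    p = params or DesignParameters()
    seqs = _sequences(genome)
    seq = seqs[target.chrom]
    lo = target.start - p.flank_allowance
    hi = target.end + p.flank_allowance
    lengths = range(p.probe_len_min, p.probe_len_max + 1, p.probe_len_step)
    out: list[CandidateProbe] = []
    start = lo
    while start + p.probe_len_min <= hi:
        if start >= 0:
            for length in lengths:
                end = start + length
                if end > hi or end > len(seq):
                    break
                probe_seq = seq[start:end]
                if "N" in probe_seq:
                    continue
                out.append(CandidateProbe(target.chrom, start, length, probe_seq))
        start += p.tile_step
    if not out:
        log.warning(
            "target %s:%d-%d too short for any probe (span %d < min length %d)",
            target.chrom, target.start, target.end, hi - max(lo, 0), p.probe_len_min,
        )
    return out


def evaluate_candidates(
    candidates: Sequence[CandidateProbe],
    kindex: KmerIndex,
    searcher: CloseMatchSearcher,
    params: DesignParameters,
) -> None:
    """Populate scores and flags in place.

    Repetitive candidates are removed from consideration before uniqueness
    scoring, mirroring the published order; their close-match count, Tm
    and composition stay unpopulated.
    """
    for c in candidates:
        c.repetitiveness = probe_repetitiveness(c.sequence, kindex)
        c.repetitive = c.repetitiveness > params.repetitive_threshold
        if c.repetitive:
            continue
        c.close_matches = searcher.count(c.sequence)
        # the origin locus is always part of the count; if it should not
        # consume one of the allowed placements, raise the cap by one
        cap = params.max_close_matches + (0 if params.count_origin_locus else 1)
        c.nonunique = c.close_matches > cap
        c.tm = melting_temperature(c.sequence, params)
        c.composition_penalty = composition_penalty(c.sequence, params)
        if not c.nonunique:
            c.score = score_probe(c, params)


@dataclass
class ProbeSet:
    probes: list = field(default_factory=list)
    params: DesignParameters = field(default_factory=DesignParameters)
    selection_log: list = field(default_factory=list)

    def __len__(self):
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)


def select_probes(
    target: TargetRegion,
    candidates: Sequence[CandidateProbe],
    params: DesignParameters | None = None,
) -> list[CandidateProbe]:
    """Windowed selection: starting at ``target.start − flank``, look at
    eligible candidates whose start lies in a ``window_len``-base window,
    compare the ``probes_per_window`` lowest-scoring and keep the single
    best (ties: leftmost, then shortest); advance the window by
    ``window_advance`` until it passes ``target.end + flank``.
    """
    p = params or DesignParameters()
    eligible = [c for c in candidates if c.passed and c.score is not None]
    selected: list[CandidateProbe] = []
    seen: set[tuple[int, int]] = set()
    w = target.start - p.flank_allowance
    end_bound = target.end + p.flank_allowance
    n_windows = 0
    while w < end_bound:
        n_windows += 1
        in_window = [c for c in eligible if w <= c.start < w + p.window_len]
        if in_window:
            in_window.sort(key=lambda c: (c.score, c.start, c.length))
            best = in_window[: p.probes_per_window][0]
            key = (best.start, best.length)
            if key not in seen:
                seen.add(key)
                selected.append(best)
        w += p.window_advance
    return selected


# --- coverage ----------------------------------------------------------------


@dataclass
class CoverageReport:
    direct_bases: int
    indirect_bases: int
    uncovered_bases: int
    per_target: list  # rows: (chrom, start, end, direct, indirect, uncovered)

    @property
    def total_bases(self) -> int:
        return self.direct_bases + self.indirect_bases + self.uncovered_bases


def _covered_in(
    start: int, end: int, intervals: Sequence[tuple[int, int]]
) -> int:
    total = 0
    for a, b in intervals:
        lo, hi = max(start, a), min(end, b)
        if lo < hi:
            total += hi - lo
    return total


def coverage_report(
    probes: ProbeSet | Sequence[CandidateProbe],
    targets: RegionSet,
    indirect_reach: int | None = None,
) -> CoverageReport:
    """Classify every target base as direct (under a probe), indirect
    (within ``indirect_reach`` bases of a probe terminus but not under
    one), or uncovered."""
    if isinstance(probes, ProbeSet):
        reach = probes.params.indirect_reach if indirect_reach is None else indirect_reach
        probe_list = probes.probes
    else:
        reach = 100 if indirect_reach is None else indirect_reach
        probe_list = list(probes)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in probe_list:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    direct_iv = {ch: merge_hit_intervals(iv) for ch, iv in by_chrom.items()}
    reach_iv = {
        ch: merge_hit_intervals((max(0, a - reach), b + reach) for a, b in iv)
        for ch, iv in direct_iv.items()
    }
    rows = []
    tot_d = tot_i = tot_u = 0
    for r in targets:
        d = _covered_in(r.start, r.end, direct_iv.get(r.chrom, ()))
        near = _covered_in(r.start, r.end, reach_iv.get(r.chrom, ()))
        i = near - d
        u = r.length - near
        rows.append((r.chrom, r.start, r.end, d, i, u))
        tot_d += d
        tot_i += i
        tot_u += u
    return CoverageReport(tot_d, tot_i, tot_u, rows)


# --- orchestration -----------------------------------------------------------


def design_exome(
    genome,
    features: Iterable[Feature],
    params: DesignParameters | None = None,
    out_prefix: str | None = None,
) -> tuple[ProbeSet, CoverageReport]:
    """Run the full design: consolidate features, index k-mers, tile,
    filter, score, select per window, and report coverage.  Deterministic
    for identical inputs and parameters."""
    p = params or DesignParameters()
    targets = consolidate_targets(features)
    kindex = build_kmer_index(genome, p.k, canonical=p.canonical_kmers)
    searcher = CloseMatchSearcher(genome, p)
    probe_set = ProbeSet(params=p)
    seen: set[tuple[str, int, int]] = set()
    for target in targets:
        cands = tile_candidates(target, genome, p)
        evaluate_candidates(cands, kindex, searcher, p)
        chosen = select_probes(target, cands, p)
        entry = {
            "target": (target.chrom, target.start, target.end),
            "genes": sorted(target.source_gene_ids),
            "n_candidates": len(cands),
            "n_selected": len(chosen),
        }
        if not chosen:
            entry["note"] = "no eligible probe in any window"
        probe_set.selection_log.append(entry)
        for c in chosen:
            key = (c.chrom, c.start, c.length)
            if key not in seen:
                seen.add(key)
                probe_set.probes.append(c)
    probe_set.probes.sort(key=lambda c: (c.chrom, c.start, c.length))
    report = coverage_report(probe_set, targets)
    if out_prefix is not None:
        _write_outputs(out_prefix, probe_set, targets, report, p)
    return probe_set, report


def _write_outputs(prefix, probe_set, targets, report, params) -> None:
    with open(f"{prefix}.probes.bed", "w", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for c in probe_set:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.chrom}:{c.start}-{c.end}"
                f"\t{round(c.score * 100)}\t.\n"
            )
    with open(f"{prefix}.probes.fasta", "w", newline="\n") as fh:
        for c in probe_set:
            fh.write(f">{c.chrom}:{c.start}-{c.end}\n{c.sequence}\n")
    write_bed(targets, f"{prefix}.targets.bed")
    with open(f"{prefix}.coverage.tsv", "w", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\tdirect\tindirect\tuncovered\n")
        for row in report.per_target:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(f"{prefix}.design.log", "w", newline="\n") as fh:
        fh.write("#parameter\tvalue\n")
        for name in params.__dataclass_fields__:
            fh.write(f"{name}\t{getattr(params, name)}\n")
        fh.write(f"n_targets\t{len(targets)}\n")
        fh.write(f"target_bases\t{targets.total_bases}\n")
        fh.write(f"n_probes\t{len(probe_set)}\n")
        fh.write(f"direct_bases\t{report.direct_bases}\n")
        fh.write(f"indirect_bases\t{report.indirect_bases}\n")
        fh.write(f"uncovered_bases\t{report.uncovered_bases}\n")
        for entry in probe_set.selection_log:
            if entry.get("note"):
                ch, s, e = entry["target"]
                fh.write(f"zero_probe_target\t{ch}:{s}-{e}\n")
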
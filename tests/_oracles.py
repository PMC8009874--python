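"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by the most direct method
available (full scans, closed forms) and share no search machinery with
the package implementations they check.
"""

import math

import numpy as np

from exomekit.probe_design import merge_hit_intervals, reverse_complement

_ENC = {c: i for i, c in enumerate("ACGTN")}


def oracle_close_matches(sequence, genome, w=30, max_edits=5):
    """Count close-match loci by full-scan semi-global DP.

    Every w-base window of the probe (and its reverse complement) is
    aligned against every chromosome with free start/end; end positions
    with edit distance <= max_edits become loci after merging overlapping
    same-strand intervals.
    """
    seqs = {k: (v.sequence if hasattr(v, "sequence") else str(v)) for k, v in genome.items()}
    texts = {ch: np.array([_ENC[c] for c in s]) for ch, s in seqs.items()}
    ends = {}
    for j in range(len(sequence) - w + 1):
        win = sequence[j : j + w]
        if "N" in win:
            continue
        for strand, pat in (("+", win), ("-", reverse_complement(win))):
            p = np.array([_ENC[c] for c in pat])
            for ch, t in texts.items():
                n = len(t)
                prev = np.zeros(n + 1, dtype=np.int32)
                idx = np.arange(n + 1)
                for i in range(1, w + 1):
                    cost = (t != p[i - 1]).astype(np.int32)
                    cur = np.empty(n + 1, dtype=np.int32)
                    cur[0] = i
                    cur[1:] = np.minimum(prev[:-1] + cost, prev[1:] + 1)
                    # exact left-propagation of the insertion recurrence
                    cur = np.minimum.accumulate(cur - idx) + idx
                    prev = cur
                hit = np.nonzero(prev[1:] <= max_edits)[0] + 1
                if len(hit):
                    ends.setdefault((ch, strand), set()).update(int(h) for h in hit)
    n_loci = 0
    for hit_ends in ends.values():
        intervals = [(max(0, e - w), e) for e in sorted(hit_ends)]
        n_loci += len(merge_hit_intervals(intervals))
    return n_loci


def oracle_kmer_counts(genome, k, canonical=True):
    """Recount k-mers by direct dictionary accumulation."""
    seqs = {n: (v.sequence if hasattr(v, "sequence") else str(v)) for n, v in genome.items()}
    counts = {}
    for s in seqs.values():
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                rc = reverse_complement(kmer)
                kmer = min(kmer, rc)
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def oracle_repetitiveness(probe, genome, k=15, canonical=True):
    counts = oracle_kmer_counts(genome, k, canonical)
    vals = []
    for i in range(len(probe) - k + 1):
        kmer = probe[i : i + k]
        if "N" in kmer:
            vals.append(0)
            continue
        if canonical:
            kmer = min(kmer, reverse_complement(kmer))
        vals.append(counts.get(kmer, 0))
    return sum(vals) / len(vals)


# unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def oracle_tm_nn(seq, na_mM=50.0, dnac_nM=0.25):
    """Nearest-neighbor melting temperature from the unified parameter
    table, with the entropic salt correction 0.368*(N-1)*ln[Na+]."""
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    R = 1.987
    k = dnac_nM * 1e-9
    return dh * 1000.0 / (ds + R * math.log(k)) - 273.15
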
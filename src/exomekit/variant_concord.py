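"""Paired-platform variant comparison.

Reproduces the published comparison order: the two call sets are first
classified into common/exclusive variants (matching on exact chromosome,
position, reference and alternate alleles), and hard filtering is applied
afterwards per platform — which is why the common count can differ
slightly between platforms.  Downstream tables are computed on passing,
biallelic records of a single variant type (SNV or indel).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

from exomekit.reference_io import RegionSet

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
STAT_KEYS = ("QD", "FS", "SOR", "MQ", "ReadPosRankSum", "MQRankSum")
IMPACTS = ("high", "moderate", "low")


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: tuple
    vtype: str  # {SNV, indel, other}
    biallelic: bool
    stats: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)  # sample -> (a0, a1); None = missing
    gene: str | None = None
    consequence: str | None = None
    impact: str | None = None
    filter_pass: bool | None = None
    failed_rules: tuple = ()
    shared: str | None = None  # {common, exclusive}

    @property
    def alt(self) -> str:
        return ",".join(self.alts)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def allele_count(self) -> int:
        ac = 0
        for gt in self.genotypes.values():
            for a in gt:
                if a is not None and a > 0:
                    ac += 1
        return ac


def _classify_type(ref: str, alts: Sequence[str]) -> tuple[str, bool]:
    biallelic = len(alts) == 1
    if not biallelic:
        return "other", False
    alt = alts[0]
    if len(ref) == 1 and len(alt) == 1 and ref != alt:
        return "SNV", True
    if len(ref) != len(alt):
        return "indel", True
    return "other", True


def load_vcf(path, sample_subset: Sequence[str] | None = None) -> list[VariantRecord]:
    """Read VCF 4.x into VariantRecords.

    Multi-allelic sites are retained but flagged non-biallelic.  Missing
    INFO stat keys leave the stat absent.  A VCF with sample columns but
    no GT FORMAT definition is an error.
    """
    vcf = VCF(str(path))
    if sample_subset is not None:
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)
    if samples and "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: sample columns present but no GT FORMAT field")
    records: list[VariantRecord] = []
    for v in vcf:
        ref = v.REF.upper()
        alts = tuple(a.upper() for a in v.ALT)
        vtype, biallelic = _classify_type(ref, alts)
        stats = {}
        for key in STAT_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                stats[key] = float(val)
        genotypes = {}
        for name, gt in zip(samples, v.genotypes):
            a0 = gt[0] if gt[0] >= 0 else None
            a1 = gt[1] if len(gt) > 2 and gt[1] >= 0 else None
            genotypes[name] = (a0, a1)
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=ref,
                alts=alts,
                vtype=vtype,
                biallelic=biallelic,
                stats=stats,
                genotypes=genotypes,
            )
        )
    return records


# --- hard filtering ----------------------------------------------------------


@dataclass(frozen=True)
class FilterThresholds:
    """GATK-style hard-filter rules; a record meeting ANY rule fails.

    Each rule is (stat, op, cutoff) with op "<" meaning fail when
    stat < cutoff and ">" meaning fail when stat > cutoff.
    """

    snv: tuple = (
        ("QD", "<", 2.0),
        ("FS", ">", 60.0),
        ("SOR", ">", 3.0),
        ("ReadPosRankSum", "<", -8.0),
        ("MQ", "<", 40.0),
        ("MQRankSum", "<", -12.5),
    )
    indel: tuple = (
        ("QD", "<", 2.0),
        ("FS", ">", 200.0),
        ("SOR", ">", 10.0),
        ("ReadPosRankSum", "<", -20.0),
    )

    def rules_for(self, vtype: str) -> tuple:
        return self.indel if vtype == "indel" else self.snv


DEFAULT_THRESHOLDS = FilterThresholds()


def apply_hard_filters(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> Counter:
    """Tag each record pass/fail in place; nothing is deleted.

    A missing stat makes its rule inapplicable (cannot fail the record).
    Returns per-rule failure counts for the audit log.
    """
    th = thresholds or DEFAULT_THRESHOLDS
    rule_fail: Counter = Counter()
    for r in records:
        failed = []
        for stat, op, cutoff in th.rules_for(r.vtype):
            val = r.stats.get(stat)
            if val is None:
                continue
            if (op == "<" and val < cutoff) or (op == ">" and val > cutoff):
                failed.append(f"{stat}{op}{cutoff}")
                rule_fail[f"{r.vtype}:{stat}"] += 1
        r.failed_rules = tuple(failed)
        r.filter_pass = not failed
    return rule_fail


def restrict_to_targets(
    records: Iterable[VariantRecord],
    targets: RegionSet,
    flank_trim: int = 2,
) -> list[VariantRecord]:
    """Keep records whose position falls within a target region shrunk by
    ``flank_trim`` bases at each end (variants in the flanking +/- trim
    zone are removed)."""
    import bisect

    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for ch, regions in targets.by_chrom().items():
        starts, ends = [], []
        for r in regions:
            s, e = r.start + flank_trim, r.end - flank_trim
            if s < e:
                starts.append(s)
                ends.append(e)
        by_chrom[ch] = (starts, ends)
    kept = []
    for rec in records:
        starts_ends = by_chrom.get(rec.chrom)
        if not starts_ends:
            continue
        starts, ends = starts_ends
        pos0 = rec.pos - 1
        i = bisect.bisect_right(starts, pos0) - 1
        if i >= 0 and pos0 < ends[i]:
            kept.append(rec)
    return kept


# --- common/exclusive classification -----------------------------------------


@dataclass
class PlatformPair:
    label_a: str
    label_b: str
    variants_a: list
    variants_b: list
    classification: dict = field(default_factory=dict)


def classify_shared(pair: PlatformPair) -> dict:
    """Label every variant in either set common or platform-exclusive.

    Common means identical (chrom, pos, ref, alt) in both sets; a shared
    position with different alleles is exclusive in both.  Classification
    runs before filtering.
    """
    keys_a = {r.key for r in pair.variants_a}
    keys_b = {r.key for r in pair.variants_b}
    classification: dict = {}
    for r in pair.variants_a:
        r.shared = "common" if r.key in keys_b else "exclusive"
        classification[r.key] = "common" if r.key in keys_b else "exclusive_a"
    for r in pair.variants_b:
        r.shared = "common" if r.key in keys_a else "exclusive"
        if r.key not in keys_a:
            classification[r.key] = "exclusive_b"
    return classification


# --- summary statistics ------------------------------------------------------


def titv_ratio(records: Iterable[VariantRecord]) -> float | None:
    """Transition/transversion ratio over biallelic SNVs; None when no
    transversions are present (undefined, not infinity)."""
    ti = tv = 0
    for r in records:
        if r.vtype != "SNV" or not r.biallelic:
            continue
        if (r.ref, r.alts[0]) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


@dataclass
class Spectrum:
    counts: dict  # allele count (>= 1) -> number of sites
    zero_sites: int

    @property
    def total_sites(self) -> int:
        return sum(self.counts.values())


def allele_count_spectrum(records: Iterable[VariantRecord]) -> Spectrum:
    """Histogram of per-site alternate allele count across all samples."""
    counts: Counter = Counter()
    zero = 0
    for r in records:
        ac = r.allele_count
        if ac >= 1:
            counts[ac] += 1
        else:
            zero += 1
    return Spectrum(dict(sorted(counts.items())), zero)


# --- consequence tables ------------------------------------------------------


def load_annotations(path) -> dict:
    """Read a consequence TSV (chrom, pos, ref, alt, gene, consequence,
    impact) into a key-indexed mapping."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "impact"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        out[key] = (row.gene, row.consequence, row.impact.lower())
    return out


def annotate(records: Iterable[VariantRecord], annotations: Mapping) -> None:
    """Join gene/consequence/impact onto records; unjoined records get
    impact 'modifier' (excluded from consequence tables)."""
    for r in records:
        ann = annotations.get(r.key)
        if ann is None:
            r.impact = "modifier"
        else:
            r.gene, r.consequence, r.impact = ann


def percentage_split(common: int, exclusive: int) -> tuple[float, float]:
    """Common/exclusive percentages of their total, rounded to 1 decimal."""
    total = common + exclusive
    if total == 0:
        return (0.0, 0.0)
    return (round(100.0 * common / total, 1), round(100.0 * exclusive / total, 1))


def _table_rows(records: Sequence[VariantRecord], vtype: str) -> Counter:
    c: Counter = Counter()
    for r in records:
        if r.vtype != vtype or not r.biallelic or not r.filter_pass:
            continue
        if r.impact not in IMPACTS:
            continue
        c[(r.impact, r.consequence or "unannotated", r.shared)] += 1
    return c


def consequence_table(pair: PlatformPair, vtype: str = "SNV") -> pd.DataFrame:
    """Per-(impact, consequence) common/exclusive counts and percentages
    for both platforms, with per-impact and overall rollups.

    Records must already be annotated, classified and filter-tagged.
    Empty categories are omitted.
    """
    counts = {"a": _table_rows(pair.variants_a, vtype), "b": _table_rows(pair.variants_b, vtype)}
    cats = sorted(
        {(imp, cons) for side in counts.values() for (imp, cons, _s) in side},
        key=lambda t: (IMPACTS.index(t[0]), t[1]),
    )
    rows = []

    def add_row(impact, consequence, selector):
        row = {"impact": impact, "consequence": consequence}
        for side, label in (("a", pair.label_a), ("b", pair.label_b)):
            com = sum(n for (imp, cons, s), n in counts[side].items()
                      if s == "common" and selector(imp, cons))
            exc = sum(n for (imp, cons, s), n in counts[side].items()
                      if s == "exclusive" and selector(imp, cons))
            pct_c, pct_e = percentage_split(com, exc)
            row.update({
                f"{label}_common": com,
                f"{label}_common_pct": pct_c,
                f"{label}_exclusive": exc,
                f"{label}_exclusive_pct": pct_e,
                f"{label}_total": com + exc,
            })
        rows.append(row)

    for impact, consequence in cats:
        add_row(impact, consequence,
                lambda i, c, I=impact, C=consequence: i == I and c == C)
    for impact in IMPACTS:
        if any(imp == impact for imp, _c in cats):
            add_row(impact, "All", lambda i, c, I=impact: i == I)
    add_row("All", "All", lambda i, c: True)
    return pd.DataFrame(rows)
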
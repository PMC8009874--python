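"""Seeded synthetic genomes, annotations and paired platform call sets.

The generator emulates the statistical structure the concordance and bias
analyses assume, at desk scale:

* a toy genome with one embedded tandem repeat family (defeats k-mer
  repetitiveness filtering), one cluster of near-identical paralog genes
  (defeats close-match uniqueness), and multi-exon genes on several
  chromosomes including one X-like chromosome;
* paired platform call sets with a controlled shared fraction, platform-
  exclusive error sites that are singletons (allele count 1), and
  male-only platform-b-exclusive sites on the X-like chromosome
  concentrated in K designated genes at a configured allele-count peak
  (emulating reads from degraded Y-chromosome gametologs mis-mapping to
  the X copy when no Y is in the reference);
* transition probabilities set separately for shared and exclusive sites
  so Ti/Tv ratios differ between the classes, and per-rule hard-filter
  failures injected at a configured fraction.

One global seed drives a named stream per component (genome, placement,
genotypes, stats, annotation), so changing one spec field perturbs only
its own stream.  All outputs are deterministic, byte for byte, per seed.

The genotype model for shared sites (allele frequency uniform on
[0.05, 0.5], genotypes binomial) is deliberately simple — adequate for
spectrum-shape and recovery testing, not population-genetically realistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from exomekit.reference_io import Feature, GenomeSequence

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

_SNV_CONSEQUENCES = [
    ("stop_gained", "high", 0.0017),
    ("splice_donor", "high", 0.0010),
    ("splice_acceptor", "high", 0.0007),
    ("missense", "moderate", 0.3020),
    ("splice_region", "low", 0.0270),
    ("synonymous", "low", 0.6676),
]
_INDEL_CONSEQUENCES = [
    ("frameshift", "high", 0.35),
    ("inframe_deletion", "moderate", 0.17),
    ("inframe_insertion", "moderate", 0.13),
    ("splice_region", "low", 0.35),
]


@dataclass
class FixtureSpec:
    """All knobs of the synthetic study, with desk-scale defaults.

    The cohort structure (10 samples, 4 males), the shared fraction, the
    transition probabilities for shared vs exclusive sites, and the
    male allele-count peak of 4 mirror the paired-cohort conditions the
    analyses are designed around; exclusive-site rates keep the published
    ~1 : 2.6 platform asymmetry but are scaled up so a toy target set
    yields enough exclusive sites to measure.
    """

    seed: int = 0
    n_chroms: int = 3  # last one is the X-like chromosome
    x_name: str = "chrX"
    chrom_length: int = 18_000
    n_genes: int = 18
    exons_per_gene: int = 4
    exon_length: int = 120
    intron_length: int = 150
    repeat_unit_length: int = 60
    repeat_copies: int = 150
    paralog_genes: int = 3
    paralog_divergence: float = 0.02
    n_samples: int = 10
    n_males: int = 4
    shared_fraction: float = 0.985
    exclusive_rate_a: float = 1.0  # exclusive sites per target kb, platform a
    exclusive_rate_b: float = 2.6
    ti_prob_common: float = 0.797  # Ti/Tv ~ 3.92 among shared SNVs
    ti_prob_exclusive: float = 0.603  # Ti/Tv ~ 1.52 among exclusive SNVs
    indel_fraction: float = 0.05
    male_only_x_genes: int = 4
    male_x_sites_per_gene: int = 12
    wgs_male_ac_peak: int = 4
    filter_fail_fraction: float = 0.05
    label_a: str = "WES"
    label_b: str = "WGS"

    def __post_init__(self):
        for name in ("shared_fraction", "paralog_divergence", "ti_prob_common",
                     "ti_prob_exclusive", "indel_fraction", "filter_fail_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_males > self.n_samples:
            raise ValueError("n_males must be <= n_samples")
        if self.exclusive_rate_a < 0 or self.exclusive_rate_b < 0:
            raise ValueError("exclusive rates must be non-negative")

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def sex_of(self) -> dict[str, str]:
        return {
            s: ("M" if i < self.n_males else "F")
            for i, s in enumerate(self.samples)
        }


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("genome", "placement", "genotypes", "stats", "annotation")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


# --- reference ---------------------------------------------------------------


def simulate_reference(spec: FixtureSpec):
    """Toy genome + CDS annotation.

    Returns (genome: {name: GenomeSequence}, features: [Feature]).  The
    repeat array sits on the first chromosome after its genes; the last
    ``paralog_genes`` genes of the second chromosome are near-identical
    copies of its first gene; the last ``male_only_x_genes`` genes on the
    X-like chromosome are the designated male-bias genes.
    """
    rng = _streams(spec.seed)["genome"]
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms - 1)] + [spec.x_name]
    per_chrom = spec.n_genes // spec.n_chroms
    extra = spec.n_genes - per_chrom * spec.n_chroms
    gene_counts = [per_chrom + (1 if i < extra else 0) for i in range(spec.n_chroms)]

    gene_span = spec.exons_per_gene * spec.exon_length + (
        spec.exons_per_gene - 1
    ) * spec.intron_length
    margin, gap = 300, 200

    arrays: dict[str, np.ndarray] = {}
    features: list[Feature] = []
    gene_idx = 0
    for ci, (chrom, n_genes) in enumerate(zip(chrom_names, gene_counts)):
        seq = rng.integers(0, 4, spec.chrom_length)
        needed = margin + n_genes * gene_span + max(0, n_genes - 1) * gap + margin
        if ci == 0:
            needed += spec.repeat_unit_length * spec.repeat_copies + margin
        if needed > spec.chrom_length:
            raise ValueError(
                f"{chrom}: layout needs {needed} bases but chrom_length is "
                f"{spec.chrom_length}"
            )
        pos = margin
        for _g in range(n_genes):
            gene_idx += 1
            gid = f"g{gene_idx:03d}"
            for e in range(spec.exons_per_gene):
                start = pos + e * (spec.exon_length + spec.intron_length)
                features.append(
                    Feature(chrom, start, start + spec.exon_length, "+", "CDS", gid)
                )
            pos += gene_span + gap
        if ci == 0 and spec.repeat_copies > 0:
            unit = rng.integers(0, 4, spec.repeat_unit_length)
            arr_start = pos + margin - gap
            array = np.tile(unit, spec.repeat_copies)
            seq[arr_start : arr_start + len(array)] = array
        arrays[chrom] = seq

    # paralog cluster: overwrite exon sequences of the last `paralog_genes`
    # genes on chromosome 2 with mutated copies of its first gene's exons
    if spec.paralog_genes > 1 and spec.n_chroms >= 2:
        chrom2 = chrom_names[1]
        c2_feats = [f for f in features if f.chrom == chrom2]
        c2_genes = sorted({f.gene_id for f in c2_feats})
        if spec.paralog_genes > len(c2_genes):
            raise ValueError("paralog_genes exceeds genes available on chromosome 2")
        template_gene = c2_genes[-spec.paralog_genes]
        copies = c2_genes[-spec.paralog_genes + 1 :]
        template_exons = [f for f in c2_feats if f.gene_id == template_gene]
        seq = arrays[chrom2]
        for gid in copies:
            for tmpl, tgt in zip(
                template_exons, [f for f in c2_feats if f.gene_id == gid]
            ):
                block = seq[tmpl.start : tmpl.end].copy()
                mut = rng.random(len(block)) < spec.paralog_divergence
                block[mut] = (block[mut] + rng.integers(1, 4, mut.sum())) % 4
                seq[tgt.start : tgt.end] = block

    genome = {
        name: GenomeSequence(name, "".join(_BASES[arr]))
        for name, arr in arrays.items()
    }
    return genome, features


def paralog_gene_ids(spec: FixtureSpec, features: Sequence[Feature]) -> list[str]:
    chrom2 = f"chr2" if spec.n_chroms >= 2 else None
    genes = sorted({f.gene_id for f in features if f.chrom == chrom2})
    return genes[-spec.paralog_genes :] if spec.paralog_genes > 1 else []


def male_bias_gene_ids(spec: FixtureSpec, features: Sequence[Feature]) -> list[str]:
    x_genes = sorted({f.gene_id for f in features if f.chrom == spec.x_name})
    if spec.male_only_x_genes > len(x_genes):
        raise ValueError("male_only_x_genes exceeds genes on the X-like chromosome")
    return x_genes[len(x_genes) - spec.male_only_x_genes :]


def repeat_array_interval(spec: FixtureSpec) -> tuple[str, int, int]:
    """Location of the tandem repeat array on the first chromosome."""
    per_chrom = spec.n_genes // spec.n_chroms
    extra = spec.n_genes - per_chrom * spec.n_chroms
    n_genes = per_chrom + (1 if extra > 0 else 0)
    gene_span = spec.exons_per_gene * spec.exon_length + (
        spec.exons_per_gene - 1
    ) * spec.intron_length
    margin, gap = 300, 200
    start = margin + n_genes * gene_span + (n_genes - 1) * gap + margin
    return "chr1", start, start + spec.repeat_unit_length * spec.repeat_copies


# --- paired call sets --------------------------------------------------------


@dataclass
class SimSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str
    cls: str  # {common, exclusive_a, exclusive_b}
    gene: str
    genotypes: list  # per sample (a0, a1)
    stats_a: dict | None
    stats_b: dict | None
    consequence: str
    impact: str
    male_x: bool = False

    @property
    def allele_count(self) -> int:
        return sum(a for gt in self.genotypes for a in gt)


@dataclass
class PlatformPairFixture:
    spec: FixtureSpec
    samples: list
    sites: list  # SimSite, sorted by (chrom order, pos)

    def sites_for(self, side: str) -> list:
        want = {"common", f"exclusive_{side}"}
        return [s for s in self.sites if s.cls in want]


def _draw_stats(rng, vtype: str, fail_fraction: float) -> dict:
    pass_ranges = {
        "QD": (15.0, 35.0), "FS": (0.0, 10.0), "SOR": (0.5, 2.5),
        "MQ": (55.0, 60.0), "ReadPosRankSum": (-2.0, 2.0), "MQRankSum": (-2.0, 2.0),
    }
    if vtype == "indel":
        fail_ranges = {
            "QD": (0.1, 1.9), "FS": (201.0, 400.0), "SOR": (10.1, 20.0),
            "ReadPosRankSum": (-30.0, -20.1),
        }
    else:
        fail_ranges = {
            "QD": (0.1, 1.9), "FS": (61.0, 150.0), "SOR": (3.1, 8.0),
            "MQ": (10.0, 39.0), "ReadPosRankSum": (-12.0, -8.1),
            "MQRankSum": (-20.0, -12.6),
        }
    stats = {}
    for key, (lo, hi) in pass_ranges.items():
        if key in fail_ranges and rng.random() < fail_fraction:
            flo, fhi = fail_ranges[key]
            stats[key] = round(float(rng.uniform(flo, fhi)), 3)
        else:
            stats[key] = round(float(rng.uniform(lo, hi)), 3)
    return stats


def _draw_alt(rng, ref: str, ti_prob: float) -> str:
    if rng.random() < ti_prob:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(0, 2)]


def _draw_consequence(rng, vtype: str) -> tuple[str, str]:
    table = _SNV_CONSEQUENCES if vtype == "SNV" else _INDEL_CONSEQUENCES
    probs = np.array([w for _c, _i, w in table])
    probs = probs / probs.sum()
    i = rng.choice(len(table), p=probs)
    return table[i][0], table[i][1]


def simulate_platform_pair(
    spec: FixtureSpec, genome=None, features=None
) -> PlatformPairFixture:
    """Draw the paired call sets over the reference's exons.

    Site classes are i.i.d. (common with probability ``shared_fraction``;
    the exclusive remainder split by the two platform rates), positions
    are drawn without replacement so the truth table and classification
    can agree exactly.  Common sites get binomial genotypes from a
    uniform allele frequency; exclusive sites are singleton hets; male-X
    sites are hets in ``wgs_male_ac_peak`` male samples only.
    """
    if genome is None or features is None:
        genome, features = simulate_reference(spec)
    rngs = _streams(spec.seed)
    place, geno, stat, annot = (
        rngs["placement"], rngs["genotypes"], rngs["stats"], rngs["annotation"]
    )
    chrom_order = {name: i for i, name in enumerate(genome)}
    male_genes = set(male_bias_gene_ids(spec, features))
    samples = spec.samples
    n_males = spec.n_males

    # position pools: (chrom, pos0, gene) per exon base
    pool: list[tuple[str, int, str]] = []
    male_pool: dict[str, list[tuple[str, int]]] = {g: [] for g in male_genes}
    for f in features:
        if f.kind != "CDS":
            continue
        for p in range(f.start, f.end):
            if f.gene_id in male_genes:
                male_pool[f.gene_id].append((f.chrom, p))
            else:
                pool.append((f.chrom, p, f.gene_id))
    gene_of = {(c, p): g for c, p, g in pool}

    kb = len(pool) / 1000.0
    rate_sum = spec.exclusive_rate_a + spec.exclusive_rate_b
    f_shared = spec.shared_fraction
    if f_shared < 1.0:
        n_sites = int(round(rate_sum * kb / (1.0 - f_shared)))
        p_a = (1.0 - f_shared) * (spec.exclusive_rate_a / rate_sum) if rate_sum else 0.0
        p_b = (1.0 - f_shared) * (spec.exclusive_rate_b / rate_sum) if rate_sum else 0.0
    else:
        n_sites = int(round(rate_sum * kb))
        p_a = p_b = 0.0
    n_sites = min(n_sites, len(pool))

    idx = place.choice(len(pool), size=n_sites, replace=False)
    idx.sort()
    classes = place.choice(
        ["common", "exclusive_a", "exclusive_b"],
        size=n_sites,
        p=[1.0 - p_a - p_b, p_a, p_b],
    )

    sites: list[SimSite] = []
    for i, cls in zip(idx, classes):
        chrom, pos0, gene = pool[i]
        vtype = "indel" if place.random() < spec.indel_fraction else "SNV"
        ref_base = genome[chrom].sequence[pos0]
        ti_p = spec.ti_prob_common if cls == "common" else spec.ti_prob_exclusive
        if vtype == "SNV":
            ref, alt = ref_base, _draw_alt(place, ref_base, ti_p)
        else:
            if place.random() < 0.5 and pos0 + 2 <= genome[chrom].length:
                ref = genome[chrom].sequence[pos0 : pos0 + 2]
                alt = ref_base
            else:
                ref = ref_base
                alt = ref_base + str(_BASES[place.integers(0, 4)])
        if cls == "common":
            af = geno.uniform(0.05, 0.5)
            gts = [tuple(sorted(geno.binomial(1, af, 2))) for _ in samples]
        else:
            carrier = int(geno.integers(0, len(samples)))
            gts = [(0, 1) if j == carrier else (0, 0) for j in range(len(samples))]
        consequence, impact = _draw_consequence(annot, vtype)
        sites.append(
            SimSite(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, vtype=vtype, cls=cls,
                gene=gene, genotypes=gts,
                stats_a=None, stats_b=None,
                consequence=consequence, impact=impact,
            )
        )

    # male-only X-like exclusive sites for platform b, concentrated in the
    # designated genes at the configured allele-count peak
    n_carrier_males = min(spec.wgs_male_ac_peak, n_males)
    for gene in sorted(male_genes):
        positions = male_pool[gene]
        take = min(spec.male_x_sites_per_gene, len(positions))
        sel = place.choice(len(positions), size=take, replace=False)
        sel.sort()
        for j in sel:
            chrom, pos0 = positions[j]
            ref = genome[chrom].sequence[pos0]
            alt = _draw_alt(place, ref, spec.ti_prob_exclusive)
            gts = [
                (0, 1) if k < n_carrier_males else (0, 0)
                for k in range(len(samples))
            ]
            consequence, impact = _draw_consequence(annot, "SNV")
            sites.append(
                SimSite(
                    chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, vtype="SNV",
                    cls="exclusive_b", gene=gene, genotypes=gts,
                    stats_a=None, stats_b=None,
                    consequence=consequence, impact=impact, male_x=True,
                )
            )

    sites.sort(key=lambda s: (chrom_order[s.chrom], s.pos, s.ref, s.alt))
    for s in sites:
        if s.cls in ("common", "exclusive_a"):
            s.stats_a = _draw_stats(stat, s.vtype, spec.filter_fail_fraction)
        if s.cls in ("common", "exclusive_b"):
            s.stats_b = _draw_stats(stat, s.vtype, spec.filter_fail_fraction)
    return PlatformPairFixture(spec=spec, samples=samples, sites=sites)


# --- writers -----------------------------------------------------------------


def write_fasta(genome, path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, gs in genome.items():
            fh.write(f">{name}\n")
            seq = gs.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features: Sequence[Feature], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        counters: dict[str, int] = {}
        for f in features:
            counters[f.gene_id] = counters.get(f.gene_id, 0) + 1
            fid = f"{f.kind.lower()}_{f.gene_id}_{counters[f.gene_id]}"
            fh.write(
                f"{f.chrom}\texomekit\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={fid};gene_id={f.gene_id}\n"
            )


_GT_STR = {(0, 0): "0/0", (0, 1): "0/1", (1, 1): "1/1"}


def write_vcf(fixture: PlatformPairFixture, genome, side: str, path) -> None:
    """Write one platform's call set as an uncompressed VCF 4.2 file."""
    sites = fixture.sites_for(side)
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=exomekit-synthetic platform={side}\n")
        for name, gs in genome.items():
            fh.write(f"##contig=<ID={name},length={gs.length}>\n")
        for key in ("QD", "FS", "SOR", "MQ", "ReadPosRankSum", "MQRankSum"):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(fixture.samples)
            + "\n"
        )
        for s in sites:
            stats = s.stats_a if side == "a" else s.stats_b
            info = ";".join(f"{k}={v}" for k, v in stats.items())
            gt_str = "\t".join(_GT_STR[gt] for gt in s.genotypes)
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t{info}\tGT\t{gt_str}\n"
            )


def write_annotation_tsv(fixture: PlatformPairFixture, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#chrom\tpos\tref\talt\tgene\tconsequence\timpact\n")
        seen = set()
        for s in fixture.sites:
            key = (s.chrom, s.pos, s.ref, s.alt)
            if key in seen:
                continue
            seen.add(key)
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.gene}\t"
                f"{s.consequence}\t{s.impact}\n"
            )


def write_sex_map(spec: FixtureSpec, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#sample_id\tsex\n")
        for s, sex in spec.sex_of.items():
            fh.write(f"{s}\t{sex}\n")


def write_truth(fixture: PlatformPairFixture, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#chrom\tpos\tref\talt\tvtype\tclass\tgene\tmale_x\n")
        for s in fixture.sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.vtype}\t{s.cls}\t"
                f"{s.gene}\t{int(s.male_x)}\n"
            )


def generate(spec: FixtureSpec, out_dir) -> dict:
    """Write the complete fixture set; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, features = simulate_reference(spec)
    fixture = simulate_platform_pair(spec, genome, features)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "genes.gff3",
        "vcf_a": out / "a.vcf",
        "vcf_b": out / "b.vcf",
        "annotations_tsv": out / "ann.tsv",
        "sex_map": out / "sex.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(features, paths["annotation"])
    write_vcf(fixture, genome, "a", paths["vcf_a"])
    write_vcf(fixture, genome, "b", paths["vcf_b"])
    write_annotation_tsv(fixture, paths["annotations_tsv"])
    write_sex_map(spec, paths["sex_map"])
    write_truth(fixture, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
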
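"""Gene-wise platform bias and sex-bias statistics.

Per-individual counts use carrier counting by default: an individual
counts a site when it carries at least one alternate allele.  Sex fold
change per gene is log2((mean male count + 1)/(mean female count + 1));
the added ones avoid division by zero.  Sex-difference percentages are
expressed as a fraction of the male mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from exomekit.variant_concord import VariantRecord

log = logging.getLogger(__name__)

INTERGENIC = "__intergenic__"


def load_sex_map(path) -> dict[str, str]:
    """Read a sample sex map TSV (sample_id, sex in {M, F, U})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    out = {}
    for row in df.itertuples(index=False):
        sex = row.sex.upper()
        if sex not in {"M", "F", "U"}:
            raise ValueError(f"{path}: invalid sex {row.sex!r} for {row.sample_id}")
        out[row.sample_id] = sex
    return out


@dataclass
class GeneCountMatrix:
    labels: tuple  # (label_a, label_b)
    site_counts: pd.DataFrame  # index gene, columns labels
    union_counts: pd.Series  # distinct sites per gene across both platforms
    indiv_counts: dict  # label -> DataFrame (gene x sample)
    gene_chrom: dict  # gene -> chromosome
    coding_len: dict  # gene -> consolidated CDS bases (may be empty)
    intergenic: dict  # label -> count of sites with no gene


def _carrier(gt) -> bool:
    return any(a is not None and a > 0 for a in gt)


def _dose(gt) -> int:
    return sum(1 for a in gt if a is not None and a > 0)


def per_gene_counts(
    records_a: Sequence[VariantRecord],
    records_b: Sequence[VariantRecord],
    labels: tuple = ("a", "b"),
    features: Iterable | None = None,
    allele_dose: bool = False,
) -> GeneCountMatrix:
    """Site-level and per-individual variant counts per gene and platform.

    Records must carry gene assignments (see ``annotate``); sites without
    one go to a reserved intergenic bucket excluded from gene tables.
    When ``features`` (CDS Features) are given, per-gene consolidated
    coding lengths are computed for SNVs-per-kb.
    """
    score = _dose if allele_dose else (lambda gt: int(_carrier(gt)))
    genes: set = set()
    gene_chrom: dict = {}
    site: dict = {}
    union_keys: dict = {}
    indiv: dict = {}
    intergenic = {}
    samples_by_label = {}
    for label, records in zip(labels, (records_a, records_b)):
        site[label] = {}
        indiv[label] = {}
        intergenic[label] = 0
        samples: list = []
        for r in records:
            if not samples and r.genotypes:
                samples = list(r.genotypes)
            if not r.gene:
                intergenic[label] += 1
                continue
            genes.add(r.gene)
            gene_chrom.setdefault(r.gene, r.chrom)
            site[label][r.gene] = site[label].get(r.gene, 0) + 1
            union_keys.setdefault(r.gene, set()).add(r.key)
            per = indiv[label].setdefault(r.gene, {})
            for sample, gt in r.genotypes.items():
                per[sample] = per.get(sample, 0) + score(gt)
        samples_by_label[label] = samples
    gene_list = sorted(genes)
    site_df = pd.DataFrame(
        {label: [site[label].get(g, 0) for g in gene_list] for label in labels},
        index=gene_list,
    )
    union = pd.Series({g: len(union_keys.get(g, ())) for g in gene_list})
    indiv_dfs = {}
    for label in labels:
        samples = samples_by_label[label]
        indiv_dfs[label] = pd.DataFrame(
            {s: [indiv[label].get(g, {}).get(s, 0) for g in gene_list] for s in samples},
            index=gene_list,
        )
    coding_len: dict = {}
    if features is not None:
        from exomekit.reference_io import consolidate_targets

        by_gene: dict = {}
        for f in features:
            by_gene.setdefault(f.gene_id, []).append(f)
        for g, fs in by_gene.items():
            coding_len[g] = consolidate_targets(fs).total_bases
    return GeneCountMatrix(
        labels=tuple(labels),
        site_counts=site_df,
        union_counts=union,
        indiv_counts=indiv_dfs,
        gene_chrom=gene_chrom,
        coding_len=coding_len,
        intergenic=intergenic,
    )


def platform_bias(
    matrix: GeneCountMatrix, top_n: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene platform difference rows plus the top-N outliers.

    difference = count_b − count_a (positive = more platform-b variants);
    expected = mean of the two counts; snvs_per_kb = distinct sites across
    both platforms per kb of coding sequence.  Outliers are the N largest
    positive differences, ties broken by gene id.
    """
    la, lb = matrix.labels
    df = matrix.site_counts.copy()
    df.columns = [f"count_{la}", f"count_{lb}"]
    df["difference"] = df[f"count_{lb}"] - df[f"count_{la}"]
    df["expected"] = (df[f"count_{la}"] + df[f"count_{lb}"]) / 2.0
    kb = pd.Series(
        {g: matrix.coding_len.get(g, 0) / 1000.0 for g in df.index}
    )
    df["snvs_per_kb"] = [
        round(matrix.union_counts[g] / kb[g], 3) if kb[g] > 0 else float("nan")
        for g in df.index
    ]
    df.index.name = "gene"
    outliers = (
        df.reset_index()
        .sort_values(["difference", "gene"], ascending=[False, True])
        .head(top_n)
        .set_index("gene")
    )
    return df, outliers


def _split_by_sex(samples: Sequence[str], sex_map: Mapping[str, str]):
    males = [s for s in samples if sex_map.get(s) == "M"]
    females = [s for s in samples if sex_map.get(s) == "F"]
    unknown = [s for s in samples if sex_map.get(s, "U") == "U"]
    if unknown:
        log.warning("excluding %d sample(s) without sex label: %s", len(unknown), unknown)
    return males, females


def sex_bias_per_gene(
    matrix: GeneCountMatrix, sex_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene, per-platform fold change
    log2((mean_male + 1)/(mean_female + 1)); NaN when a sex is absent."""
    out = {}
    for label in matrix.labels:
        indiv = matrix.indiv_counts[label]
        males, females = _split_by_sex(indiv.columns, sex_map)
        if not males or not females:
            out[label] = pd.Series(float("nan"), index=indiv.index)
            continue
        mm = indiv[males].mean(axis=1)
        mf = indiv[females].mean(axis=1)
        out[label] = (mm + 1.0).div(mf + 1.0).apply(math.log2)
    df = pd.DataFrame(out)
    df.index.name = "gene"
    return df


def sex_difference_from_means(mean_m: float, mean_f: float) -> tuple[float, float]:
    """Absolute male-female difference and its percentage of the male
    mean, both rounded to 2 decimals."""
    diff = abs(mean_m - mean_f)
    if mean_m == 0:
        raise ValueError("male mean is zero; percentage undefined")
    return round(diff, 2), round(100.0 * diff / mean_m, 2)


def sex_difference_summary(
    matrix: GeneCountMatrix,
    sex_map: Mapping[str, str],
    gene_groupings: Mapping[str, Sequence[str]] | None = None,
    x_chrom: str = "chrX",
) -> pd.DataFrame:
    """Mean variants per individual by sex, for each gene grouping x
    platform x chromosome class (autosome vs X)."""
    groupings = dict(gene_groupings or {})
    groupings.setdefault("all", list(matrix.site_counts.index))
    rows = []
    for gname, genes in groupings.items():
        unknown = [g for g in genes if g not in matrix.gene_chrom]
        if unknown:
            raise ValueError(f"grouping {gname!r} references unknown genes: {unknown}")
        for label in matrix.labels:
            indiv = matrix.indiv_counts[label]
            males, females = _split_by_sex(indiv.columns, sex_map)
            for cls in ("autosome", "X"):
                sel = [
                    g for g in genes
                    if (matrix.gene_chrom[g] == x_chrom) == (cls == "X")
                ]
                sub = indiv.loc[sel]
                totals = sub.sum(axis=0)
                mean_m = float(totals[males].mean()) if males else float("nan")
                mean_f = float(totals[females].mean()) if females else float("nan")
                if males and mean_m > 0:
                    diff, pct = sex_difference_from_means(mean_m, mean_f)
                else:
                    diff, pct = float("nan"), float("nan")
                rows.append(
                    {
                        "grouping": gname,
                        "platform": label,
                        "chrom_class": cls,
                        "mean_male": round(mean_m, 2),
                        "mean_female": round(mean_f, 2),
                        "difference": diff,
                        "pct_of_male_mean": pct,
                    }
                )
    return pd.DataFrame(rows)
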
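"""Multi-locus haplotype classes at chosen focal markers.

An inbred accession carries one allele per locus, so the combination of
homozygous alleles at a handful of focal SNPs defines its haplotype
class (at most 2^L classes for L biallelic loci).  Classes are labeled
Hap1..HapK ordered by ascending alternative-allele count — all-reference
first, all-alternative last — with ties broken by descending frequency;
an explicit anchor ordering can force a fixed layout.  Trait differences
among classes are tested by one-way ANOVA with Tukey's HSD post hoc test
(Tukey-Kramer for unbalanced classes) and summarized as a compact letter
display: classes sharing a letter are not significantly different.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeTable:
    """Accession haplotype assignments at the focal markers."""

    marker_ids: list[str]
    assignments: pd.DataFrame  # accession, allele_string, class_label
    class_order: list[str]  # allele strings, Hap1 first
    n_excluded: int  # heterozygous/missing accessions dropped

    def class_counts(self) -> pd.Series:
        counts = self.assignments["class_label"].value_counts()
        return counts.reindex(
            [f"Hap{i + 1}" for i in range(len(self.class_order))], fill_value=0
        )

    @property
    def n_classes(self) -> int:
        return self.assignments["class_label"].nunique()


def build_haplotypes(
    G: GenotypeMatrix,
    marker_ids: Sequence[str],
    anchor_order: Sequence[str] | None = None,
) -> HaplotypeTable:
    """Assign each fully homozygous accession its allele combination.

    The allele string concatenates the ref (dosage 0) or alt (dosage 2)
    base per locus in the given marker order.  Heterozygous or missing
    accessions are excluded with a logged count.  ``anchor_order`` forces
    an explicit allele-string ordering (observed strings absent from the
    anchor follow it, in the default order).
    """
    idx = [G.marker_index(mid) for mid in marker_ids]
    sub = G.dosages[:, idx]
    refs = [G.markers[i].ref for i in idx]
    alts = [G.markers[i].alt for i in idx]

    complete = np.all((sub == 0) | (sub == 2), axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info(
            "build_haplotypes: excluded %d accessions heterozygous or missing "
            "at a focal marker", n_excluded,
        )
    accs = [a for a, ok in zip(G.accession_ids, complete) if ok]
    strings = [
        "".join(alts[j] if d == 2 else refs[j] for j, d in enumerate(row))
        for row, ok in zip(sub, complete) if ok
    ]
    ser = pd.Series(strings, index=accs)

    counts = ser.value_counts()
    observed = list(counts.index)
    alt_count = {
        s: sum(ch == alts[j] for j, ch in enumerate(s)) for s in observed
    }
    default_order = sorted(observed, key=lambda s: (alt_count[s], -counts[s], s))
    if anchor_order is not None:
        anchored = [s for s in anchor_order if s in observed]
        rest = [s for s in default_order if s not in anchored]
        order = anchored + rest
    else:
        order = default_order

    label_of = {s: f"Hap{i + 1}" for i, s in enumerate(order)}
    assignments = pd.DataFrame(
        {
            "accession": accs,
            "allele_string": strings,
            "class_label": [label_of[s] for s in strings],
        }
    )
    return HaplotypeTable(
        marker_ids=list(marker_ids), assignments=assignments,
        class_order=order, n_excluded=n_excluded,
    )


def haplotype_group_stats(
    table: HaplotypeTable, trait_values: pd.Series
) -> pd.DataFrame:
    """Per-class n, mean and SD (n-1 denominator) for one trait.

    Singleton classes report their mean with SD as NaN and a flag;
    classes with no trait values are omitted with a warning.
    """
    merged = table.assignments.merge(
        trait_values.rename("value"), left_on="accession", right_index=True, how="left"
    ).dropna(subset=["value"])
    rows = []
    for i, allele in enumerate(table.class_order):
        label = f"Hap{i + 1}"
        vals = merged.loc[merged["class_label"] == label, "value"].to_numpy()
        if vals.size == 0:
            logger.warning("haplotype_group_stats: class %s (%s) empty, omitted", label, allele)
            continue
        rows.append(
            {
                "class_label": label,
                "allele_string": allele,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size >= 2 else np.nan,
                "sd_undefined": vals.size < 2,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise tests and letter display."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    alpha: float


def _compact_letter_display(
    groups: Sequence[str], not_different: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letters: groups share a letter iff no
    significant pairwise difference separates them."""
    letter_sets: list[set[str]] = [set(groups)]
    for g1, g2 in combinations(groups, 2):
        if (g1, g2) in not_different or (g2, g1) in not_different:
            continue
        # g1 and g2 differ: split every set containing both
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            s1, s2 = s - {g2}, s - {g1}
            for cand in (s1, s2):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    # absorb: drop sets contained in another (defensive; loop above checks)
    letter_sets = [
        s for s in letter_sets
        if not any(s < other for other in letter_sets)
    ]
    # stable letter assignment by first group in input order
    order_key = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order_key[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for li, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                letters[g] += alphabet[li % len(alphabet)]
    return letters


def anova_tukey_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA F-test plus Tukey HSD at family-wise ``alpha``.

    Pairwise p-values come from the studentized-range distribution with
    the Tukey-Kramer harmonic-mean adjustment for unequal group sizes.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InputError("need >= 2 groups with >= 2 observations each")

    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    n_total = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    ss_between = float(sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrays)))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, n_total - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f_stat = ms_b / ms_w if ms_w > 0 else np.inf
    p_val = float(stats.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0

    rows = []
    not_different: set[tuple[str, str]] = set()
    for (i, g1), (j, g2) in combinations(enumerate(names), 2):
        diff = arrays[j].mean() - arrays[i].mean()
        se = np.sqrt(ms_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))  # Tukey-Kramer
        q = np.abs(diff) / se if se > 0 else np.inf
        p_adj = float(stats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        reject = p_adj < alpha
        if not reject:
            not_different.add((g1, g2))
        rows.append(
            {"group1": g1, "group2": g2, "meandiff": diff, "p_adj": p_adj, "reject": reject}
        )
    letters = _compact_letter_display(names, not_different)
    return AnovaTukeyResult(
        f_statistic=f_stat, p_value=p_val,
        pairwise=pd.DataFrame(rows), letters=letters, alpha=alpha,
    )
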
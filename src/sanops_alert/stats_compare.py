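"""Descriptive and nonparametric comparison of utility-class samples.

One sample is an ordered list of utility classes (integers 1-5) per
terminology.  The omnibus comparison is the Kruskal-Wallis test
(tie-corrected H, chi-square p with k-1 df); pairwise comparisons use the
two-sided rank-sum test under the normal approximation with continuity
and tie correction, which is the standard choice at n around 100 with
heavy ties.  No multiple-testing correction is applied; the report says
so explicitly.

Note on "standard deviation": the per-group dispersion reported here is
the sample standard deviation (ddof=1), not the standard error of the
mean.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .errors import SanopsError

__all__ = [
    "ClassSample",
    "GroupDescription",
    "ComparisonReport",
    "describe",
    "kruskal_wallis",
    "wilcoxon_pairwise",
    "comparison_report",
]

_NO_CORRECTION_NOTE = (
    "pairwise p-values are uncorrected for multiple testing (no "
    "Bonferroni/Holm adjustment is applied)"
)


class ClassSample:
    """Terminology name -> ordered list of utility classes in {1..5}."""

    def __init__(self, groups: dict[str, "list[int]"]) -> None:
        if not groups:
            raise SanopsError("sample must contain at least one group")
        self._groups: dict[str, list[int]] = {}
        for name, values in groups.items():
            values = [int(v) for v in values]
            if not values:
                raise SanopsError(f"group {name!r} is empty")
            bad = [v for v in values if v not in (1, 2, 3, 4, 5)]
            if bad:
                raise SanopsError(
                    f"group {name!r} contains values outside 1..5: {bad[:5]}"
                )
            self._groups[name] = values

    @property
    def groups(self) -> dict[str, list[int]]:
        return dict(self._groups)

    @property
    def names(self) -> list[str]:
        return list(self._groups)

    def __len__(self) -> int:
        return len(self._groups)

    @classmethod
    def coerce(cls, sample: "ClassSample | dict") -> "ClassSample":
        return sample if isinstance(sample, cls) else cls(sample)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassSample":
        """Read (terminology, exam_code, class) rows."""
        groups: dict[str, list[int]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                groups.setdefault(row["terminology"], []).append(
                    int(row["class"])
                )
        return cls(groups)


@dataclass(frozen=True)
class GroupDescription:
    terminology: str
    n: int
    median: float
    mode: int
    mean: float
    sd: float
    mean_rank: float


def _pooled_mean_ranks(sample: ClassSample) -> dict[str, float]:
    """Per-group mean of pooled mid-ranks."""
    names = sample.names
    pooled = np.concatenate([sample.groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    out: dict[str, float] = {}
    offset = 0
    for name in names:
        size = len(sample.groups[name])
        out[name] = float(ranks[offset : offset + size].mean())
        offset += size
    return out


def describe(sample: "ClassSample | dict") -> list[GroupDescription]:
    """Median, mode, mean, sample SD and pooled mean rank per group.

    Mode ties break toward the smaller class.  A single-observation group
    reports SD 0.0.
    """
    sample = ClassSample.coerce(sample)
    mean_ranks = _pooled_mean_ranks(sample)
    out: list[GroupDescription] = []
    for name in sample.names:
        values = np.asarray(sample.groups[name], dtype=float)
        counts = {c: int((values == c).sum()) for c in (1, 2, 3, 4, 5)}
        mode = min(
            (c for c in counts), key=lambda c: (-counts[c], c)
        )
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        out.append(
            GroupDescription(
                terminology=name,
                n=len(values),
                median=float(np.median(values)),
                mode=mode,
                mean=float(values.mean()),
                sd=sd,
                mean_rank=mean_ranks[name],
            )
        )
    return out


def kruskal_wallis(
    sample: "ClassSample | dict",
) -> tuple[float, float, dict[str, float]]:
    """Tie-corrected Kruskal-Wallis H, chi-square p, and mean ranks."""
    sample = ClassSample.coerce(sample)
    if len(sample) < 2:
        raise SanopsError("Kruskal-Wallis needs at least two groups")
    groups = [sample.groups[n] for n in sample.names]
    pooled = [v for g in groups for v in g]
    if len(set(pooled)) == 1:
        # all observations identical: no evidence of any difference
        return 0.0, 1.0, _pooled_mean_ranks(sample)
    h, p = sps.kruskal(*groups)
    return float(h), float(p), _pooled_mean_ranks(sample)


def _ranksum_p(x: "list[int]", y: "list[int]") -> float:
    """Two-sided rank-sum p, normal approximation with continuity and tie
    correction (Mann-Whitney form)."""
    if len(set(x) | set(y)) == 1:
        return 1.0
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def wilcoxon_pairwise(
    sample: "ClassSample | dict", alpha: float = 0.05
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], bool]]:
    """Symmetric pairwise rank-sum p-value matrix and significance flags."""
    sample = ClassSample.coerce(sample)
    if len(sample) < 2:
        raise SanopsError("pairwise comparison needs at least two groups")
    if not 0 < alpha < 1:
        raise SanopsError("alpha must be in (0, 1)")
    pvalues: dict[tuple[str, str], float] = {}
    flags: dict[tuple[str, str], bool] = {}
    names = sample.names
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = _ranksum_p(sample.groups[a], sample.groups[b])
            for key in ((a, b), (b, a)):
                pvalues[key] = p
                flags[key] = p < alpha
    return pvalues, flags


@dataclass(frozen=True)
class ComparisonReport:
    """Full descriptive + omnibus + pairwise comparison."""

    alpha: float
    descriptions: tuple[GroupDescription, ...]
    h_statistic: float
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    notes: tuple[str, ...] = (_NO_CORRECTION_NOTE,)

    @property
    def names(self) -> list[str]:
        return [d.terminology for d in self.descriptions]

    def to_csv(self, path: str | Path) -> None:
        """Render descriptive rows then the pairwise p matrix."""
        names = self.names
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([f"# alpha={self.alpha}; {'; '.join(self.notes)}"])
            writer.writerow(
                ["descriptive statistic"] + names
            )
            rows = [
                ("median utility class", lambda d: d.median),
                ("mode utility class", lambda d: d.mode),
                ("mean utility class", lambda d: round(d.mean, 4)),
                ("standard deviation", lambda d: round(d.sd, 4)),
                ("mean rank", lambda d: round(d.mean_rank, 4)),
            ]
            by_name = {d.terminology: d for d in self.descriptions}
            for label, getter in rows:
                writer.writerow([label] + [getter(by_name[n]) for n in names])
            writer.writerow([])
            writer.writerow(
                ["omnibus H", round(self.h_statistic, 4),
                 "p", _fmt_p(self.omnibus_p)]
            )
            writer.writerow([])
            writer.writerow(["pairwise p"] + names)
            for a in names:
                writer.writerow(
                    [a]
                    + [
                        "" if a == b else _fmt_p(self.pairwise_p[(a, b)])
                        for b in names
                    ]
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "notes": list(self.notes),
            "groups": [
                {
                    "terminology": d.terminology,
                    "n": d.n,
                    "median": d.median,
                    "mode": d.mode,
                    "mean": d.mean,
                    "sd": d.sd,
                    "mean_rank": d.mean_rank,
                }
                for d in self.descriptions
            ],
            "kruskal_wallis": {"H": self.h_statistic, "p": self.omnibus_p},
            "pairwise": [
                {
                    "a": a,
                    "b": b,
                    "p": p,
                    "significant": self.significant[(a, b)],
                }
                for (a, b), p in sorted(self.pairwise_p.items())
                if a < b
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _fmt_p(p: float) -> str:
    return "<.001" if p < 0.001 else f"{p:.3f}"


def comparison_report(
    sample: "ClassSample | dict", alpha: float = 0.05
) -> ComparisonReport:
    """Assemble descriptives, omnibus test, and pairwise matrix."""
    sample = ClassSample.coerce(sample)
    descriptions = tuple(describe(sample))
    h, p, _ranks = kruskal_wallis(sample)
    pairwise, flags = wilcoxon_pairwise(sample, alpha)
    return ComparisonReport(
        alpha=alpha,
        descriptions=descriptions,
        h_statistic=h,
        omnibus_p=p,
        pairwise_p=pairwise,
        significant=flags,
    )
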
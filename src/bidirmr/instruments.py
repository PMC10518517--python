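"""Instrument selection: significance thresholding, LD clumping, strength
and confounder screens, and LD-proxy substitution.

Instruments are SNPs that predict the exposure strongly (genome-wide
significance, or a relaxed 1e-5 threshold when fewer than three genome-wide
significant SNPs exist), independently (greedy LD clumping at r^2 < 0.001),
and without evidence of association with measured confounders or the outcome
(Bonferroni screen at 0.05 / number of testable SNPs).  Instrument strength
is summarised by

    R^2 = 2 * EAF * (1 - EAF) * beta^2
    F   = R^2 * (N - 2) / (1 - R^2)

and SNPs with F < 10 are excluded as weak.  Variants missing from the
outcome dataset may be replaced by LD proxies at r^2 > 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .summary_io import SummaryDataset

logger = logging.getLogger("bidirmr")

__all__ = [
    "LDReference",
    "InstrumentDiagnostics",
    "choose_p_threshold",
    "clump",
    "compute_r_squared",
    "compute_f_statistic",
    "filter_weak",
    "screen_confounders_and_outcome",
    "find_proxies",
]

STRICT_P = 5e-8
RELAXED_P = 1e-5


class LDReference:
    """Symmetric lookup of pairwise squared LD correlations.

    Absent pairs are treated as r^2 = 0; r^2(a, a) = 1 by definition.
    ``window`` records the maximum bp distance at which pairs were stored.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None,
                 window: int | None = None):
        self._pairs: dict[frozenset, float] = {}
        self.window = window
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 out of [0,1]: {r2}")
        if a != b:
            self._pairs[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), 0.0)

    def neighbours(self, a: str) -> dict[str, float]:
        """All variants with a stored nonzero pair against ``a``."""
        out: dict[str, float] = {}
        for key, r2 in self._pairs.items():
            if a in key:
                (other,) = key - {a}
                out[other] = r2
        return out

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_table(cls, path, window: int | None = None) -> "LDReference":
        """Load a tab-separated table with columns variant_a, variant_b, r2.

        The symmetric closure is applied on load.
        """
        df = pd.read_csv(path, sep="\t")
        ref = cls(window=window)
        for a, b, r2 in zip(df["variant_a"], df["variant_b"], df["r2"]):
            ref.set(str(a), str(b), float(r2))
        return ref

    def to_table(self, path) -> None:
        rows = [(sorted(k)[0], sorted(k)[1], v) for k, v in self._pairs.items()]
        pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


@dataclass
class InstrumentDiagnostics:
    """Per-instrument strength diagnostics and exclusion bookkeeping."""

    variant_id: str
    r_squared: float
    f_statistic: float
    excluded_reason: str | None = None


def choose_p_threshold(dataset: SummaryDataset, strict: float = STRICT_P,
                       relaxed: float = RELAXED_P, min_gs_snps: int = 3) -> float:
    """Pick the instrument p-value threshold for an exposure.

    Uses genome-wide significance (5e-8) when at least ``min_gs_snps``
    variants reach it, otherwise the relaxed 1e-5 threshold.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    n_gs = int((dataset.table["p_value"] < strict).sum())
    if n_gs >= min_gs_snps:
        logger.info("%s: %d genome-wide significant SNPs -> strict threshold %.0e",
                    dataset.trait_id, n_gs, strict)
        return strict
    logger.info("%s: only %d genome-wide significant SNPs -> relaxed threshold %.0e",
                dataset.trait_id, n_gs, relaxed)
    return relaxed


def clump(dataset: SummaryDataset, threshold: float, ld: LDReference | None,
          r2_max: float = 0.001, window_bp: int = 10_000_000,
          pre_clumped: bool = False) -> list[str]:
    """Greedy LD clumping of sub-threshold variants.

    Candidates with p < threshold are ranked by ascending p (variant id
    breaks ties so the result is order-invariant); the best is kept and all
    remaining candidates within ``window_bp`` on the same chromosome with
    r^2 >= r2_max against it are removed, repeatedly.
    """
    tab = dataset.table
    cand = tab[tab["p_value"] < threshold]
    if len(cand) == 0:
        return []
    if pre_clumped:
        return sorted(cand["variant_id"], key=lambda v: (cand.loc[v, "p_value"], v))
    if ld is None:
        raise ValueError("no LD reference supplied and dataset not flagged pre-clumped")

    order = cand.sort_values(["p_value", "variant_id"], kind="mergesort")
    remaining = list(order["variant_id"])
    pos = dict(zip(order["variant_id"], order["position"]))
    chrom = dict(zip(order["variant_id"], order["chromosome"]))
    kept: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        survivors = []
        for v in remaining:
            same_chrom = chrom[v] == chrom[best]
            within = same_chrom and abs(pos[v] - pos[best]) <= window_bp
            if within and ld.r2(best, v) >= r2_max:
                logger.info("clump: %s removed (r2=%.3g with %s)", v, ld.r2(best, v), best)
                continue
            survivors.append(v)
        remaining = survivors
    return kept


def compute_r_squared(eaf: float, beta: float) -> float:
    """Trait-variance proportion explained by one SNP: 2*EAF*(1-EAF)*beta^2.

    Assumes a standardized trait; values exceeding 1 (a sign the beta is not
    standardized) are clipped just below 1 with a warning.
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf out of (0,1): {eaf}")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    cap = 1.0 - 1e-12
    if r2 > cap:
        logger.warning("R^2 = %.3g exceeds 1 (non-standardized beta?); clipped", r2)
        return cap
    return r2


def compute_f_statistic(r_squared: float, n: float) -> float:
    """Instrument-strength F-statistic: R^2*(N-2)/(1-R^2)."""
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    if not (0.0 <= r_squared < 1.0):
        raise ValueError(f"r_squared out of [0,1): {r_squared}")
    return r_squared * (n - 2.0) / (1.0 - r_squared)


def diagnostics_for(dataset: SummaryDataset, variant_ids: Iterable[str]
                    ) -> list[InstrumentDiagnostics]:
    """Compute R^2 and F for each listed variant of a dataset."""
    out = []
    for vid in variant_ids:
        row = dataset.table.loc[vid]
        r2 = compute_r_squared(float(row["eaf"]), float(row["beta"]))
        f = compute_f_statistic(r2, float(row["n"]))
        out.append(InstrumentDiagnostics(vid, r2, f))
    return out


def filter_weak(instruments: Sequence[InstrumentDiagnostics], f_min: float = 10.0
                ) -> list[InstrumentDiagnostics]:
    """Drop weak instruments: F strictly below ``f_min`` is excluded.

    F exactly equal to the threshold is retained (the exclusion rule is
    F < 10).
    """
    kept = []
    for d in instruments:
        if d.f_statistic < f_min:
            d.excluded_reason = "weak"
            logger.info("weak instrument excluded: %s (F=%.3f)", d.variant_id, d.f_statistic)
        else:
            kept.append(d)
    return kept


def screen_confounders_and_outcome(
    instrument_ids: Sequence[str],
    screens: Mapping[str, SummaryDataset],
    alpha: float = 0.05,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Remove instruments associated with a confounder or the outcome.

    For each screen dataset the Bonferroni threshold is alpha divided by the
    number of instruments *present in that screen's table*; any instrument
    whose screen p-value falls below it is removed.  Instruments absent from
    a screen are retained (no evidence) and logged as not testable.

    Returns (retained ids, exclusion log).
    """
    if len(instrument_ids) == 0:
        return [], []
    excluded: dict[str, str] = {}
    log: list[tuple[str, str]] = []
    for name, ds in screens.items():
        if ds is None or len(ds) == 0:
            logger.warning("screen %s is empty; skipped", name)
            continue
        testable = [v for v in instrument_ids if v in ds]
        if not testable:
            continue
        thr = alpha / len(testable)
        for vid in instrument_ids:
            if vid not in ds:
                log.append((vid, f"not testable in {name}"))
                continue
            p = float(ds.table.loc[vid, "p_value"])
            if p < thr and vid not in excluded:
                excluded[vid] = name
                log.append((vid, f"confounder:{name}" if name not in ("outcome",)
                            else "outcome-associated"))
                logger.info("screen %s: %s excluded (p=%.3g < %.3g)", name, vid, p, thr)
    kept = [v for v in instrument_ids if v not in excluded]
    return kept, log


def find_proxies(missing: Sequence[str], ld: LDReference | None,
                 outcome: SummaryDataset, r2_min: float = 0.9
                 ) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Substitute LD proxies for instruments absent from the outcome dataset.

    Each missing variant is replaced by the outcome-present variant with the
    highest r^2 strictly above ``r2_min``; ties are broken by the smaller
    outcome p-value, then variant id.  Unproxied variants are dropped and
    logged.

    Returns (substitution map original -> proxy, drop log).
    """
    subs: dict[str, str] = {}
    dropped: list[tuple[str, str]] = []
    for vid in missing:
        best: str | None = None
        best_key: tuple | None = None
        if ld is not None:
            for cand, r2 in ld.neighbours(vid).items():
                if r2 <= r2_min or cand not in outcome:
                    continue
                p_out = float(outcome.table.loc[cand, "p_value"])
                key = (-r2, p_out, cand)  # max r2, then min p, then lexicographic
                if best_key is None or key < best_key:
                    best, best_key = cand, key
        if best is None:
            dropped.append((vid, "missing in outcome, no proxy"))
            logger.info("no proxy at r2>%.2f for %s; dropped", r2_min, vid)
        else:
            subs[vid] = best
            logger.info("proxy substitution: %s -> %s (r2=%.3f)", vid, best, -best_key[0])
    return subs, dropped
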
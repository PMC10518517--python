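"""Allele harmonization of exposure and outcome association rows.

Two-sample MR requires the SNP-exposure effect (gamma) and the SNP-outcome
effect (Gamma) to refer to the same effect allele.  For each variant shared
by the two datasets the outcome row is aligned to the exposure's orientation:

* alleles already matched - copied as-is;
* alleles swapped (exposure effect allele equals outcome other allele) -
  outcome beta negated and EAF replaced by 1 - EAF;
* alleles matching only after complementing the outcome pair (A<->T, C<->G)
  - a strand flip is applied first, then direct/swap matching;
* palindromic variants (A/T or C/G) - excluded outright, because strand
  orientation is ambiguous;
* irreconcilable allele pairs - excluded.

Standard errors are never altered; only the sign of Gamma can change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summary_io import SummaryDataset, VariantAssociation

logger = logging.getLogger("bidirmr")

__all__ = ["HarmonizedInstrumentSet", "is_palindromic", "harmonize_pair",
           "EmptyHarmonizedSetError"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: post-alignment |eaf_exp - eaf_out| above this triggers a warning (not exclusion)
EAF_DISCORDANCE_WARN = 0.2


class EmptyHarmonizedSetError(ValueError):
    """No variants survived harmonization; carries the exclusion log."""

    def __init__(self, exclusions: list[tuple[str, str]]):
        self.exclusions = exclusions
        super().__init__(f"empty harmonized set ({len(exclusions)} exclusions)")


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP (gamma, se_gamma, Gamma, se_Gamma) rows.

    ``snps`` has columns variant_id, gamma, se_gamma, Gamma, se_Gamma (index
    variant_id); ``exclusions`` logs every shared or exposure-only variant
    not retained, as (variant_id, reason).
    """

    exposure_id: str
    outcome_id: str
    snps: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def gamma(self) -> np.ndarray:
        return self.snps["gamma"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.snps["se_gamma"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.snps["Gamma"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.snps["se_Gamma"].to_numpy(float)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.snps["variant_id"])

    def subset(self, variant_ids) -> "HarmonizedInstrumentSet":
        sub = self.snps.loc[list(variant_ids)]
        return HarmonizedInstrumentSet(self.exposure_id, self.outcome_id,
                                       sub, list(self.exclusions))

    def drop(self, variant_ids) -> "HarmonizedInstrumentSet":
        keep = [v for v in self.snps.index if v not in set(variant_ids)]
        return self.subset(keep)

    @classmethod
    def from_arrays(cls, gamma, se_gamma, Gamma, se_Gamma, variant_ids=None,
                    exposure_id: str = "exposure", outcome_id: str = "outcome"
                    ) -> "HarmonizedInstrumentSet":
        """Build a harmonized set directly from effect arrays (already aligned)."""
        gamma = np.asarray(gamma, float)
        n = len(gamma)
        if variant_ids is None:
            variant_ids = [f"snp{i + 1}" for i in range(n)]
        df = pd.DataFrame({
            "variant_id": list(variant_ids),
            "gamma": gamma,
            "se_gamma": np.asarray(se_gamma, float),
            "Gamma": np.asarray(Gamma, float),
            "se_Gamma": np.asarray(se_Gamma, float),
        }).set_index("variant_id", drop=False)
        df.index.name = None
        if (df["se_gamma"] <= 0).any() or (df["se_Gamma"] <= 0).any():
            raise ValueError("standard errors must be positive")
        return cls(exposure_id, outcome_id, df)

    def to_table(self, path) -> None:
        """Serialise as TSV (the same format accepted for external instrument tables)."""
        self.snps.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_table(cls, path, exposure_id="exposure", outcome_id="outcome"
                   ) -> "HarmonizedInstrumentSet":
        df = pd.read_csv(path, sep="\t")
        return cls.from_arrays(df["gamma"], df["se_gamma"], df["Gamma"],
                               df["se_Gamma"], list(df["variant_id"]),
                               exposure_id, outcome_id)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _orient(exp: VariantAssociation, out: VariantAssociation):
    """Return (sign, aligned outcome eaf) or None if irreconcilable.

    sign = +1 for direct match, -1 for allele swap; strand complementation
    is tried only when both direct and swapped matching fail.
    """
    ea, oa = out.effect_allele, out.other_allele
    if (ea, oa) == (exp.effect_allele, exp.other_allele):
        return 1, out.eaf
    if (ea, oa) == (exp.other_allele, exp.effect_allele):
        return -1, 1.0 - out.eaf
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (exp.effect_allele, exp.other_allele):
        return 1, out.eaf
    if (cea, coa) == (exp.other_allele, exp.effect_allele):
        return -1, 1.0 - out.eaf
    return None


def harmonize_pair(exposure_rows, outcome_rows,
                   exposure_id: str = "exposure", outcome_id: str = "outcome",
                   proxy_map: dict[str, str] | None = None
                   ) -> HarmonizedInstrumentSet:
    """Align exposure and outcome rows to a common effect allele.

    Parameters
    ----------
    exposure_rows, outcome_rows
        Lists of :class:`VariantAssociation`, or :class:`SummaryDataset`.
    proxy_map
        Optional mapping exposure variant id -> outcome proxy variant id;
        proxied variants are matched through their proxy and re-checked for
        palindromy.

    Returns a :class:`HarmonizedInstrumentSet`; raises
    :class:`EmptyHarmonizedSetError` when nothing survives.
    """
    def as_map(rows):
        if isinstance(rows, SummaryDataset):
            return {vid: rows.record(vid) for vid in rows.table.index}
        return {r.variant_id: r for r in rows}

    exp_map = as_map(exposure_rows)
    out_map = as_map(outcome_rows)
    proxy_map = proxy_map or {}

    rows = []
    exclusions: list[tuple[str, str]] = []
    for vid in exp_map:
        exp = exp_map[vid]
        out_vid = proxy_map.get(vid, vid)
        if out_vid not in out_map:
            exclusions.append((vid, "missing in outcome"))
            continue
        out = out_map[out_vid]
        if is_palindromic(exp.effect_allele, exp.other_allele) or \
                is_palindromic(out.effect_allele, out.other_allele):
            exclusions.append((vid, "palindromic"))
            continue
        oriented = _orient(exp, out)
        if oriented is None:
            exclusions.append((vid, "allele mismatch"))
            continue
        sign, out_eaf = oriented
        if abs(exp.eaf - out_eaf) > EAF_DISCORDANCE_WARN:
            logger.warning("EAF discordance at %s: exposure %.3f vs outcome %.3f",
                           vid, exp.eaf, out_eaf)
        rows.append({
            "variant_id": vid,
            "gamma": exp.beta,
            "se_gamma": exp.se,
            "Gamma": sign * out.beta,
            "se_Gamma": out.se,
        })

    if not rows:
        raise EmptyHarmonizedSetError(exclusions)

    df = pd.DataFrame(rows).set_index("variant_id", drop=False)
    df.index.name = None
    return HarmonizedInstrumentSet(exposure_id, outcome_id, df, exclusions)
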
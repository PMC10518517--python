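"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator realises the instrumental-variable causal diagram: true
SNP-exposure effects gamma_j produce SNP-outcome effects

    Gamma_j = theta * gamma_j + alpha_j,

where theta is the causal effect and alpha_j a horizontal-pleiotropy term
drawn according to the scenario's pleiotropy mode (none, balanced around
zero, directional with nonzero mean on a fraction of instruments, or
correlated with gamma_j to violate the InSIDE assumption).  Observed effects
add estimation noise with allele-frequency- and sample-size-driven standard
errors, so generated SEs shrink as n^{-1/2}.

Binary outcomes are emitted on the BOLT-LMM linear scale (log-odds effects
multiplied by mu*(1-mu), mu the case fraction) so the downstream scale
conversion is exercised.  Allele-encoding quirks — palindromic variants,
strand-flipped and allele-swapped outcome rows, variants missing from the
outcome — are injected at configurable rates, and LD-block structure is
emitted as a local LD reference table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .harmonize import HarmonizedInstrumentSet
from .instruments import LDReference
from .summary_io import SummaryDataset, TraitMetadata, dataset_from_frame

__all__ = ["SimulationScenario", "SimulationTruth", "simulate_pair",
           "simulate_panel", "make_fixture_suite", "FINNGEN_CASE_FRACTION"]

#: IgA-vasculitis case fraction in the FinnGen GWAS: 470 cases, 216 099 controls
FINNGEN_CASE_FRACTION = 470.0 / 216_569.0

#: non-palindromic ordered allele pairs to draw from
_SAFE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
               ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violated")


@dataclass
class SimulationScenario:
    """Generative parameters for one exposure/outcome summary-statistic pair.

    Defaults mirror the study design the generator emulates: ~30 candidate
    instruments for a rank-normalised exposure measured in ~8 300
    individuals, against a rare binary outcome from a biobank GWAS of
    216 569 individuals (case fraction 470/216 569) reported on the BOLT-LMM
    linear scale.
    """

    n_snps: int = 30
    theta: float = 0.0
    gamma_mean: float = 0.1
    gamma_sd: float = 0.02
    n_exposure: int = 8_293
    n_outcome: int = 216_569
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 0.3
    inside_rho: float = 0.5
    outcome_binary: bool = True
    case_fraction: float = FINNGEN_CASE_FRACTION
    ld_blocks: list = field(default_factory=list)  # [(block_size, within_r2), ...]
    palindrome_rate: float = 0.0
    strand_flip_rate: float = 0.0
    allele_swap_rate: float = 0.0
    missing_in_outcome_rate: float = 0.0
    seed: int = 0
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"

    def __post_init__(self) -> None:
        for name in ("palindrome_rate", "strand_flip_rate", "allele_swap_rate",
                     "missing_in_outcome_rate", "pleiotropy_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0.0:
            raise ValueError("balanced pleiotropy requires pleiotropy_mean = 0")
        if self.outcome_binary and not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0,1) for binary outcomes")

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ld_blocks" in raw:
            raw["ld_blocks"] = [tuple(b) for b in raw["ld_blocks"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated pair; together with the generator's
    formulas it reproduces every emitted beta exactly given the seed."""

    theta: float
    gamma: np.ndarray          # true SNP-exposure effects
    alpha: np.ndarray          # pleiotropic SNP-outcome effects
    eaf: np.ndarray
    se_gamma: np.ndarray
    se_Gamma: np.ndarray       # on the emitted (linear, for binary) scale
    variant_ids: list
    conversion_divisor: float | None  # mu*(1-mu) for binary outcomes
    palindromic: np.ndarray
    strand_flipped: np.ndarray
    allele_swapped: np.ndarray
    missing_in_outcome: np.ndarray


def _se_model(eaf: np.ndarray, n: int, case_fraction: float | None = None) -> np.ndarray:
    """Approximate GWAS standard errors for a standardized trait.

    Continuous: se ~ 1/sqrt(2 p (1-p) n).  Binary (log-odds scale): the
    effective sample size is n*mu*(1-mu), giving
    se ~ 1/sqrt(2 p (1-p) n mu (1-mu)) — rare diseases yield the large
    log-odds SEs seen in practice.
    """
    n_eff = n if case_fraction is None else n * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)


def _draw_alpha(rng: np.random.Generator, sc: SimulationScenario,
                gamma: np.ndarray) -> np.ndarray:
    J = sc.n_snps
    if sc.pleiotropy_mode == "none":
        return np.zeros(J)
    if sc.pleiotropy_mode == "balanced":
        return rng.normal(0.0, sc.pleiotropy_sd, J)
    if sc.pleiotropy_mode == "directional":
        # pleiotropy oriented by the exposure-raising allele: a positive
        # pleiotropy_mean pushes the outcome up through whichever allele
        # increases the exposure, the usual directional construction
        alpha = np.zeros(J)
        invalid = rng.random(J) < sc.pleiotropy_frac
        draw = rng.normal(sc.pleiotropy_mean, sc.pleiotropy_sd, invalid.sum())
        alpha[invalid] = draw * np.sign(gamma[invalid])
        return alpha
    # inside_violated: alpha correlated with instrument strength
    noise = rng.normal(0.0, sc.pleiotropy_sd, J) if sc.pleiotropy_sd > 0 else 0.0
    return sc.inside_rho * gamma + noise


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)


def _assign_alleles(rng: np.random.Generator, J: int, palindrome_rate: float):
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    palindromic = rng.random(J) < palindrome_rate
    for j in range(J):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _SAFE_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]
    return ea, oa, palindromic


def _build_ld(variant_ids, ld_blocks) -> LDReference:
    """Emit the scenario's LD blocks as a local reference: consecutive
    variants are grouped into blocks with the stated within-block r^2."""
    ref = LDReference()
    idx = 0
    for size, r2 in ld_blocks:
        block = variant_ids[idx:idx + size]
        for i in range(len(block)):
            for k in range(i + 1, len(block)):
                ref.set(block[i], block[k], r2)
        idx += size
    return ref


def simulate_pair(scenario: SimulationScenario,
                  rng: np.random.Generator | None = None,
                  id_prefix: str = "rs",
                  chromosome: str = "1",
                  position_offset: int = 0,
                  ) -> tuple[SummaryDataset, SummaryDataset, SimulationTruth, LDReference]:
    """Generate one exposure/outcome summary-statistic pair with ground truth.

    Returns (exposure dataset, outcome dataset, truth record, LD reference).
    """
    sc = scenario
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    J = sc.n_snps
    eaf = rng.uniform(0.05, 0.95, J)
    gamma_true = rng.normal(sc.gamma_mean, sc.gamma_sd, J)
    alpha = _draw_alpha(rng, sc, gamma_true)
    Gamma_true = sc.theta * gamma_true + alpha

    se_g = _se_model(eaf, sc.n_exposure)
    mu = sc.case_fraction if sc.outcome_binary else None
    se_G = _se_model(eaf, sc.n_outcome, mu)

    gamma_obs = rng.normal(gamma_true, se_g)
    Gamma_obs = rng.normal(Gamma_true, se_G)

    divisor = None
    if sc.outcome_binary:
        divisor = mu * (1.0 - mu)
        Gamma_emit = Gamma_obs * divisor
        se_G_emit = se_G * divisor
    else:
        Gamma_emit, se_G_emit = Gamma_obs, se_G

    vids = [f"{id_prefix}{position_offset + j + 1}" for j in range(J)]
    positions = np.arange(J) * 1_000_000 + 10_000 + position_offset
    ea, oa, palindromic = _assign_alleles(rng, J, sc.palindrome_rate)

    exp_df = pd.DataFrame({
        "variant_id": vids,
        "chromosome": chromosome,
        "position": positions,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "beta": gamma_obs,
        "se": se_g,
        "p_value": _two_sided_p(gamma_obs, se_g),
        "n": sc.n_exposure,
    })

    # outcome rows: same variants, optionally strand-flipped / allele-swapped
    flip = rng.random(J) < sc.strand_flip_rate
    swap = rng.random(J) < sc.allele_swap_rate
    out_ea, out_oa = ea.copy(), oa.copy()
    out_beta, out_eaf = Gamma_emit.copy(), eaf.copy()
    for j in range(J):
        if swap[j]:
            out_ea[j], out_oa[j] = out_oa[j], out_ea[j]
            out_beta[j] = -out_beta[j]
            out_eaf[j] = 1.0 - out_eaf[j]
        if flip[j]:
            out_ea[j] = _COMPLEMENT[out_ea[j]]
            out_oa[j] = _COMPLEMENT[out_oa[j]]
    missing = rng.random(J) < sc.missing_in_outcome_rate

    out_df = pd.DataFrame({
        "variant_id": vids,
        "chromosome": chromosome,
        "position": positions,
        "effect_allele": out_ea,
        "other_allele": out_oa,
        "eaf": out_eaf,
        "beta": out_beta,
        "se": se_G_emit,
        "p_value": _two_sided_p(Gamma_obs, se_G),
        "n": sc.n_outcome,
    })[~missing]

    exposure = dataset_from_frame(exp_df, TraitMetadata(
        sc.exposure_id, "continuous", "inverse-normal"))
    outcome_meta = (TraitMetadata(sc.outcome_id, "binary", "linear-boltlmm", mu)
                    if sc.outcome_binary
                    else TraitMetadata(sc.outcome_id, "continuous", "inverse-normal"))
    outcome = dataset_from_frame(out_df, outcome_meta)

    truth = SimulationTruth(sc.theta, gamma_true, alpha, eaf, se_g, se_G_emit,
                            vids, divisor, palindromic, flip, swap, missing)
    return exposure, outcome, truth, _build_ld(vids, sc.ld_blocks)


def harmonized_from_truth(scenario: SimulationScenario,
                          rng: np.random.Generator | None = None
                          ) -> tuple[HarmonizedInstrumentSet, SimulationTruth]:
    """Directly build a harmonized instrument set from a scenario, bypassing
    allele bookkeeping — convenient for estimator calibration studies.
    Binary outcomes are converted back to the log-odds scale."""
    from .summary_io import convert_boltlmm_to_logor

    sc = dataclasses.replace(scenario, palindrome_rate=0.0, strand_flip_rate=0.0,
                             allele_swap_rate=0.0, missing_in_outcome_rate=0.0)
    exposure, outcome, truth, _ = simulate_pair(sc, rng)
    if sc.outcome_binary:
        outcome = convert_boltlmm_to_logor(outcome)
    hset = HarmonizedInstrumentSet.from_arrays(
        exposure.table["beta"], exposure.table["se"],
        outcome.table["beta"], outcome.table["se"],
        truth.variant_ids, sc.exposure_id, sc.outcome_id)
    return hset, truth


def simulate_panel(factor_count: int = 41,
                   disease_scenario: SimulationScenario | None = None,
                   seed: int = 0,
                   factor_theta: dict | None = None,
                   signal_factor: str = "IL8",
                   signal_theta: float = 0.35,
                   n_snps_per_factor: int = 15,
                   reverse_theta: dict | None = None,
                   ) -> dict:
    """Simulate the full trait panel: ``factor_count`` rank-normalised
    cytokines, two log-scale acute-phase proteins (CRP- and PCT-like) and
    one rare binary disease.

    Every factor's instruments appear as outcome rows in the disease table
    (BOLT-LMM linear scale), and the disease's own instruments appear as
    outcome rows in every factor table, so both analysis directions run off
    the same files.  By default all causal effects are zero except a single
    designated signal factor with ``theta = signal_theta`` in the forward
    direction.

    Returns a dict with keys ``factors`` (list of SummaryDataset),
    ``disease`` (SummaryDataset), ``ld`` (LDReference), ``truth`` (dict).
    """
    if factor_count < 1:
        raise ValueError("factor_count must be >= 1")
    rng = np.random.default_rng(seed)
    base = disease_scenario or SimulationScenario()
    mu = base.case_fraction
    divisor = mu * (1.0 - mu)

    names = [f"cytokine_{i + 1:02d}" for i in range(factor_count)]
    if factor_count >= 1:
        names[min(7, factor_count - 1)] = signal_factor  # IL-8-like designated signal
    names += ["CRP", "PCT"]
    scales = {n: "inverse-normal" for n in names}
    scales["CRP"] = scales["PCT"] = "natural-log"
    n_by_trait = {n: 8_293 for n in names}
    n_by_trait["CRP"], n_by_trait["PCT"] = 206_158, 3_301

    theta_map = {n: 0.0 for n in names}
    theta_map[signal_factor] = signal_theta
    if factor_theta:
        theta_map.update(factor_theta)
    rev_map = {n: 0.0 for n in names}
    if reverse_theta:
        rev_map.update(reverse_theta)

    # disease instruments (log-odds effects large enough to pass the relaxed
    # 1e-5 threshold, as for a rare biobank disease)
    J_d = 18
    d_eaf = rng.uniform(0.05, 0.95, J_d)
    d_gamma = rng.normal(0.45, 0.05, J_d) * rng.choice([-1, 1], J_d)
    d_se = _se_model(d_eaf, base.n_outcome, mu)
    d_gamma_obs = rng.normal(d_gamma, d_se)
    d_ids = [f"rsD{j + 1}" for j in range(J_d)]

    ld = LDReference()
    factors: list[SummaryDataset] = []
    disease_rows: list[pd.DataFrame] = []
    truth: dict = {"theta_forward": dict(theta_map), "theta_reverse": dict(rev_map),
                   "conversion_divisor": divisor, "signal_factor": signal_factor,
                   "disease_instruments": d_ids}

    ea_d = np.empty(J_d, dtype=object)
    oa_d = np.empty(J_d, dtype=object)
    for j in range(J_d):
        ea_d[j], oa_d[j] = _SAFE_PAIRS[rng.integers(len(_SAFE_PAIRS))]

    for i, name in enumerate(names):
        sc = SimulationScenario(
            n_snps=n_snps_per_factor, theta=theta_map[name],
            n_exposure=n_by_trait[name], n_outcome=base.n_outcome,
            outcome_binary=True, case_fraction=mu,
            exposure_id=name, outcome_id=base.outcome_id or "disease",
            seed=seed)
        exp_ds, out_ds, pair_truth, _ = simulate_pair(
            sc, rng, id_prefix=f"rs{i}_", chromosome=str(i % 22 + 1))
        # disease instruments as outcome rows in this factor's table
        rev_beta_true = rev_map[name] * d_gamma
        rev_se = _se_model(d_eaf, n_by_trait[name])
        rev_beta = rng.normal(rev_beta_true, rev_se)
        rev_df = pd.DataFrame({
            "variant_id": d_ids,
            "chromosome": "22",
            "position": np.arange(J_d) * 1_000_000 + 50_000_000,
            "effect_allele": ea_d, "other_allele": oa_d,
            "eaf": d_eaf, "beta": rev_beta, "se": rev_se,
            "p_value": _two_sided_p(rev_beta, rev_se),
            "n": n_by_trait[name],
        })
        full = pd.concat([exp_ds.table.reset_index(drop=True), rev_df],
                         ignore_index=True)
        factors.append(dataset_from_frame(full, TraitMetadata(
            name, "continuous", scales[name])))
        disease_rows.append(out_ds.table.reset_index(drop=True))
        truth[name] = pair_truth

    d_self = pd.DataFrame({
        "variant_id": d_ids,
        "chromosome": "22",
        "position": np.arange(J_d) * 1_000_000 + 50_000_000,
        "effect_allele": ea_d, "other_allele": oa_d,
        "eaf": d_eaf,
        "beta": d_gamma_obs * divisor,  # emitted on the BOLT-LMM linear scale
        "se": d_se * divisor,
        "p_value": _two_sided_p(d_gamma_obs, d_se),
        "n": base.n_outcome,
    })
    disease_df = pd.concat(disease_rows + [d_self], ignore_index=True)
    disease = dataset_from_frame(disease_df, TraitMetadata(
        base.outcome_id or "disease", "binary", "linear-boltlmm", mu))

    return {"factors": factors, "disease": disease, "ld": ld, "truth": truth}


# -- deterministic unit-test fixtures ---------------------------------------

def collinear_egger_set() -> HarmonizedInstrumentSet:
    """Exactly collinear instruments on the line Gamma = 0.05 + 2*gamma."""
    g = np.array([0.1, 0.2, 0.3])
    return HarmonizedInstrumentSet.from_arrays(
        g, np.full(3, 0.01), 0.05 + 2.0 * g, np.full(3, 0.1))


def constant_ratio_set(c: float = 1.5, J: int = 5) -> HarmonizedInstrumentSet:
    """All per-SNP ratios identical to ``c``; zero heterogeneity by design."""
    g = np.linspace(0.1, 0.5, J)
    return HarmonizedInstrumentSet.from_arrays(
        g, np.full(J, 0.01), c * g, np.full(J, 0.05))


def outlier_presso_set(J: int = 10, shift_sds: float = 10.0,
                       seed: int = 20240301) -> tuple[HarmonizedInstrumentSet, str]:
    """A clean theta = 1 set with one SNP's outcome effect shifted by
    ``shift_sds`` outcome SEs; returns (set, shifted variant id)."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.1, 0.3, J)
    sg = np.full(J, 0.01)
    sG = np.full(J, 0.05)
    G = g + rng.normal(0.0, sG * 0.2, J)
    G[J // 2] += shift_sds * sG[J // 2]
    hset = HarmonizedInstrumentSet.from_arrays(g, sg, G, sG)
    return hset, hset.variant_ids[J // 2]


def harmonization_quirk_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small exposure/outcome tables covering direct, swapped, strand-flipped,
    palindromic and missing-variant harmonization paths (hard-coded values)."""
    exp = pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "chromosome": "1",
        "position": [1000, 2000, 3000, 4000, 5000],
        "effect_allele": ["A", "A", "A", "A", "C"],
        "other_allele": ["G", "G", "G", "T", "T"],
        "eaf": [0.3, 0.3, 0.3, 0.3, 0.4],
        "beta": [0.10, 0.10, 0.10, 0.10, 0.12],
        "se": [0.01, 0.01, 0.01, 0.01, 0.01],
        "p_value": [1e-9] * 5,
        "n": 8_293,
    })
    out = pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3", "rs4"],
        "chromosome": "1",
        "position": [1000, 2000, 3000, 4000],
        "effect_allele": ["A", "G", "T", "A"],   # direct, swapped, flipped, palindromic
        "other_allele": ["G", "A", "C", "T"],
        "eaf": [0.3, 0.7, 0.3, 0.3],
        "beta": [0.05, -0.05, 0.05, 0.05],
        "se": [0.02, 0.02, 0.02, 0.02],
        "p_value": [0.01] * 4,
        "n": 216_569,
    })
    return exp, out


def make_fixture_suite(out_dir) -> dict:
    """Write the deterministic unit-test fixture families as TSV files.

    Families: collinear Egger set, constant-ratio set, single-outlier
    MR-PRESSO set, and the palindrome/strand-flip harmonization pair.
    Fixtures are seed-free or fixed-seed, so repeated calls are
    byte-identical.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    ce = collinear_egger_set()
    paths["collinear_egger"] = os.path.join(out_dir, "collinear_egger.tsv")
    ce.to_table(paths["collinear_egger"])
    cr = constant_ratio_set()
    paths["constant_ratio"] = os.path.join(out_dir, "constant_ratio.tsv")
    cr.to_table(paths["constant_ratio"])
    op, _ = outlier_presso_set()
    paths["outlier_presso"] = os.path.join(out_dir, "outlier_presso.tsv")
    op.to_table(paths["outlier_presso"])
    exp, out = harmonization_quirk_tables()
    paths["harmonization_exposure"] = os.path.join(out_dir, "harmonization_exposure.tsv")
    paths["harmonization_outcome"] = os.path.join(out_dir, "harmonization_outcome.tsv")
    exp.to_csv(paths["harmonization_exposure"], sep="\t", index=False, float_format="%.10g")
    out.to_csv(paths["harmonization_outcome"], sep="\t", index=False, float_format="%.10g")
    return paths
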
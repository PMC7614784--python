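"""End-to-end parameter-recovery benchmarks.

Each benchmark forward-simulates an assay at the study's printed
generating values and recovers the quantity of interest with the package's
own analysis stages:

* ``kd_recovery`` — quadratic-isotherm K_D from synthetic anisotropy
  titrations (ATP / ADP / ADP.AlFx ssDNA-affinity conditions);
* ``nucleation_fold_change`` — ratio of apparent nucleation rates from
  paired kymograph sets generated at 2:1 nucleation rate densities;
* ``stoichiometry_recovery`` — ATP/ADP per complex from synthetic HPLC
  chromatograms with matched standard curves (wild-type and Walker-A
  mutant compositions);
* ``atpase_reduction`` — percent loss of ATPase activity from synthetic
  TLC lanes generated at half the wild-type hydrolysis.
"""

from __future__ import annotations

import numpy as np

from . import biochem, kymo, synthgen

__all__ = [
    "kd_recovery",
    "nucleation_fold_change",
    "stoichiometry_recovery",
    "atpase_reduction",
    "run_all",
]

# Generating ssDNA dissociation constants (uM) per nucleotide condition.
KD_CONDITIONS_UM = {"ATP": 0.16, "ADP": 1.18, "ADP.AlFx": 0.09}

# Generating nucleotide compositions (uM at 1.0 uM complex).
WT_NT_UM = {"ATP": 2.1, "ADP": 1.9}
WALKER_A_NT_UM = {"ATP": 1.8, "ADP": 1.2}

# Wild-type fraction of ATP hydrolysed in the 30-min TLC assay; the
# catalytic-glutamate mutant runs at half the wild-type rate.
WT_HYDROLYSED_FRACTION = 0.4
MUTANT_RELATIVE_RATE = 0.5

INTEGRATION_WINDOWS_MIN = {"ADP": (6.0, 7.0), "ATP": (8.5, 9.5)}


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def kd_recovery(true_kd_uM: float, seed: int, n_seeds: int = 20,
                noise_sd: float = 0.005) -> dict:
    """Median fitted K_D (uM) over replicate synthetic titrations."""
    fits = []
    for s in _child_seeds(seed, n_seeds):
        titr, _ = synthgen.simulate_titration(true_kd_uM, noise_sd=noise_sd, seed=s)
        fit = biochem.fit_binding_isotherm(titr)
        if fit.converged:
            fits.append(fit)
    kds = np.array([f.kd_uM for f in fits])
    order = np.argsort(kds)
    median_fit = fits[order[len(order) // 2]]
    return {
        "median_kd_uM": float(np.median(kds)),
        "n": len(fits),
        "median_fit_ci95": median_fit.ci95_kd,
        "true_kd_uM": true_kd_uM,
    }


def _nucleation_arm_params(k_nuc: float, seed: int) -> synthgen.SimKymoParams:
    # Nucleation-dominated regime (no growth) with discrete nucleation
    # sites: the expected peak count is exactly M (1 - exp(-k_nuc p t)), so
    # the fitted exponential rate is proportional to the generating rate
    # density and the arm ratio recovers the generating fold-change.
    return synthgen.SimKymoParams(
        length_um=480.0, duration_s=200.0, frame_interval_s=2.5,
        k_nuc=k_nuc, v_grow=0.0, nucleus_footprint_nm=800.0,
        nucleation_site_period_nm=2000.0, seed=seed,
    )


def nucleation_fold_change(seed: int, n_seeds: int = 16,
                           k_nuc_stimulated: float = 0.015,
                           k_nuc_alone: float = 0.0075) -> dict:
    """Ratio of arm-median apparent nucleation rates for 2:1 generators."""
    rates = {"stimulated": [], "alone": []}
    for s in _child_seeds(seed, n_seeds):
        for arm, k_nuc in (("stimulated", k_nuc_stimulated), ("alone", k_nuc_alone)):
            km, _ = synthgen.simulate_kymograph(_nucleation_arm_params(k_nuc, s))
            est = kymo.estimate_nucleation_rate(km, "rad51")
            if est.fit.converged:
                rates[arm].append(est.apparent_rate)
    med_hi = float(np.median(rates["stimulated"]))
    med_lo = float(np.median(rates["alone"]))
    return {
        "ratio": med_hi / med_lo,
        "median_rate_stimulated_s": med_hi,
        "median_rate_alone_s": med_lo,
        "n": min(len(rates["stimulated"]), len(rates["alone"])),
    }


def stoichiometry_recovery(nt_concs_uM: dict[str, float],
                           protein_conc_uM: float = 1.0,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> biochem.StoichiometryResult:
    """Recover nt/complex from a synthetic chromatogram + matched standards."""
    chrom, _ = synthgen.simulate_chromatogram(nt_concs_uM, noise_sd=noise_sd,
                                              seed=seed)
    windows = {s: INTEGRATION_WINDOWS_MIN[s] for s in nt_concs_uM}
    standards: dict[str, list[tuple[float, float]]] = {}
    for conc in (1.0, 5.0):
        std_chrom, _ = synthgen.simulate_chromatogram(
            {s: conc for s in nt_concs_uM}, seed=seed + 1)
        table = biochem.integrate_nucleotide_peaks(
            std_chrom, windows, {s: [(1.0, 1.0), (2.0, 2.0)] for s in windows})
        for row in table.itertuples():
            standards.setdefault(str(row.species), []).append((row.area, conc))
    peaks = biochem.integrate_nucleotide_peaks(chrom, windows, standards)
    return biochem.nucleotide_stoichiometry(peaks, protein_conc_uM)


def atpase_reduction(seed: int = 0,
                     wt_fraction: float = WT_HYDROLYSED_FRACTION,
                     relative_rate: float = MUTANT_RELATIVE_RATE) -> dict:
    """Percent reduction in ATPase activity of the mutant vs wild type."""
    assay, _ = synthgen.simulate_tlc(
        [wt_fraction, wt_fraction * relative_rate], seed=seed)
    res = biochem.atpase_hydrolysis(assay)
    wt_pct, mut_pct = res.percent_hydrolysis
    return {
        "reduction_percent": 100.0 * (1.0 - mut_pct / wt_pct),
        "wt_percent_hydrolysis": float(wt_pct),
        "mutant_percent_hydrolysis": float(mut_pct),
    }


def run_all(seed: int) -> dict[str, dict]:
    """Compute every benchmark; returns {target: {value, n}}."""
    out: dict[str, dict] = {}
    for offset, (tid, cond) in enumerate([("t1", "ATP"), ("t2", "ADP"),
                                          ("t3", "ADP.AlFx")]):
        r = kd_recovery(KD_CONDITIONS_UM[cond], seed=seed + offset)
        out[tid] = {"value": r["median_kd_uM"], "n": r["n"]}

    fold = nucleation_fold_change(seed)
    out["t5"] = {"value": fold["ratio"], "n": fold["n"]}

    wt = stoichiometry_recovery(WT_NT_UM, seed=seed)
    out["t6"] = {"value": wt.nt_per_complex["ATP"], "n": 1}
    out["t7"] = {"value": wt.nt_per_complex["ADP"], "n": 1}

    mut = stoichiometry_recovery(WALKER_A_NT_UM, seed=seed)
    out["t8"] = {"value": mut.total_nt, "n": 1}

    red = atpase_reduction(seed)
    out["t9"] = {"value": red["reduction_percent"], "n": 2}
    return out
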
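"""Synthetic-data generator emulating a litter-amended peat incubation.

Everything downstream of raw spectral processing is testable against this
module: it produces LC-MS feature tables with known species -> feature maps,
an NMR-style concentration block, and CO2 flux time series with a known
litter/peat/priming decomposition.

The labeling model is uniform per-carbon Bernoulli labeling: every carbon of
a molecule is independently 13C with probability equal to the species'
enrichment (total 13C atom fraction), so isotopologue envelopes are
binomial.  Unlabeled material sits at natural abundance (1.07 at-%), and the
labeled litter default is 52.4 at-% — the enrichment level of the litter
amendment the generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .constants import C13_MASS_DIFF, P_NATURAL_13C
from .design import SampleDesign
from .tables import FeatureTable

ORIGINS = ("litter", "peat_native", "microbial_product", "peat_primed")

DEFAULT_ORIGIN_MIX = {
    "litter": 0.35,
    "peat_native": 0.35,
    "microbial_product": 0.15,
    "peat_primed": 0.15,
}


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class MolecularSpecies:
    """A ground-truth molecular species behind one isotopologue cluster.

    ``enrichment`` is the per-carbon total 13C probability (atom fraction):
    natural abundance for peat-derived species, the litter enrichment level
    for litter species.
    """

    species_id: str
    n_carbon: int
    neutral_mass: float
    rt: float
    origin: str
    enrichment: float
    base_abundance: float

    def __post_init__(self) -> None:
        if self.n_carbon < 1:
            raise ValueError("n_carbon must be >= 1")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class TableGroundTruth:
    """Ground truth for a generated feature table."""

    species: pd.DataFrame            # one row per species
    feature_map: pd.DataFrame        # feature_id -> species_id, k ("" = noise)
    true_abundance: pd.DataFrame     # species x samples, noiseless
    labeled: pd.Series               # species_id -> bool (tracer present)
    seed: int | None


@dataclass
class FluxGroundTruth:
    """Noiseless flux decomposition per jar and sampling day."""

    components: pd.DataFrame  # jar_id, treatment, day, litter, peat, priming, f_net, r_net
    config: dict
    seed: int | None


# ----------------------------------------------------------------------
# Configs
# ----------------------------------------------------------------------
@dataclass
class DynamicsConfig:
    """Per-origin abundance trajectories over the incubation.

    Defaults are set so litter-amended samples at day 7 (PL-T1) carry a
    strong transient excursion — litter compounds still abundant while the
    microbial-product pulse peaks — which a Manhattan-distance ordination
    separates from all other samples.
    """

    litter_decay: float = 0.15        # 1/day, litter species decay in PL
    pulse_amplitude: float = 3.0      # peak fold-level of microbial products in PL
    pulse_tau: float = 7.0            # day of the microbial pulse peak
    primed_decay: float = 0.04        # 1/day, peat_primed decline in PL only
    microbial_baseline: float = 0.05  # microbial products in unamended peat


@dataclass
class NoiseConfig:
    """Measurement-noise model for the feature table.

    Abundance variation (sample prep, biology) acts at the compound level
    and scales all isotopologues of one species in one sample together
    (``intensity_cv``); the residual per-cell detector noise that perturbs
    within-spectrum envelope ratios is much smaller (``envelope_cv``).
    """

    mass_ppm_sd: float = 0.5          # ppm mass error SD (ultra-high-res MS)
    rt_jitter_sd: float = 0.02        # min, RT error SD per feature
    intensity_cv: float = 0.2         # compound-level log-normal CV per sample
    envelope_cv: float = 0.05         # per-cell residual log-normal CV
    noise_feature_fraction: float = 0.1  # unassigned noise rows / signal rows
    missing_rate: float = 0.05        # per-cell dropout probability
    detection_floor: float = 1e5      # per-cell limit of detection; below -> 0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"noise parameter {name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class FluxConfig:
    """Two-pool flux simulation: peat baseline + decaying litter + priming pulse.

    Fluxes are in umol CO2 g^-1 dry peat d^-1; isotope ratios are 13C atom
    fractions of total C.  The priming pulse is ``A * t * exp(-t / tau)``.
    """

    baseline: float = 2.0
    litter_l0: float = 8.0
    litter_decay: float = 0.099       # half-life ~7 days
    priming_amplitude: float = 0.35   # peak priming ~0.9 at day 7
    priming_tau: float = 7.0
    r_soil: float = 0.0108
    r_litter: float = 0.524
    cv: float = 0.1
    n_jars: int = 2
    days: tuple = (1, 3, 5, 10, 15, 20, 25, 30, 35, 40)


# ----------------------------------------------------------------------
# Species and envelopes
# ----------------------------------------------------------------------
def generate_species(
    n_species: int,
    origin_mix: dict[str, float] | None = None,
    mass_range: tuple[float, float] = (100.0, 1200.0),
    rt_range: tuple[float, float] = (2.0, 68.0),
    enrichment: float = 0.524,
    p_nat: float = P_NATURAL_13C,
    abundance_log_mean: float = np.log(2e8),
    abundance_log_sd: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[MolecularSpecies]:
    """Draw a pool of molecular species with origins and enrichments.

    Carbon counts are drawn uniformly between ``mass/30`` and ``mass/12``
    (the elemental plausibility band for CHNOS organics).  Litter species
    get per-carbon 13C probability ``max(enrichment, p_nat)`` — a tracer
    level of zero reduces to natural abundance — all other origins sit at
    natural abundance.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    lo, hi = mass_range
    if not (lo < hi):
        raise ValueError("empty mass range")
    if origin_mix is None:
        origin_mix = dict(DEFAULT_ORIGIN_MIX)
    probs = np.array([origin_mix.get(o, 0.0) for o in ORIGINS], dtype=float)
    if probs.sum() <= 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("origin_mix proportions must sum to 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    origins = rng.choice(len(ORIGINS), size=n_species, p=probs)
    masses = rng.uniform(lo, hi, size=n_species)
    rts = rng.uniform(rt_range[0], rt_range[1], size=n_species)
    abundances = rng.lognormal(abundance_log_mean, abundance_log_sd, size=n_species)

    species = []
    for i in range(n_species):
        mass = float(masses[i])
        nc_lo = max(1, int(np.ceil(mass / 30.0)))
        nc_hi = max(nc_lo, int(np.floor(mass / 12.0)))
        n_carbon = int(rng.integers(nc_lo, nc_hi + 1))
        origin = ORIGINS[origins[i]]
        enr = max(enrichment, p_nat) if origin == "litter" else p_nat
        species.append(
            MolecularSpecies(
                species_id=f"sp_{i:04d}",
                n_carbon=n_carbon,
                neutral_mass=mass,
                rt=float(rts[i]),
                origin=origin,
                enrichment=enr,
                base_abundance=float(abundances[i]),
            )
        )
    return species


def expected_envelope(n_carbon: int, p: float) -> np.ndarray:
    """Binomial isotopologue envelope: proportions over k = 0..n_carbon."""
    return stats.binom.pmf(np.arange(n_carbon + 1), n_carbon, p)


def multinomial_envelope(
    n_carbon: int, p: float, ion_count: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample an observed envelope: ``ion_count`` ions over isotopologues."""
    if ion_count < 1:
        raise ValueError("ion_count must be >= 1")
    return rng.multinomial(ion_count, expected_envelope(n_carbon, p)).astype(float)


def simulate_envelope(
    species: MolecularSpecies,
    ion_count: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample one species' isotopologue envelope with ``ion_count`` ion draws.

    Each carbon is independently 13C with probability ``species.enrichment``;
    the resulting binomial envelope is sampled multinomially, so the returned
    vector has length ``n_carbon + 1`` and sums to ``ion_count``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    return multinomial_envelope(species.n_carbon, species.enrichment, ion_count, rng)


# ----------------------------------------------------------------------
# Feature table
# ----------------------------------------------------------------------
def _origin_multiplier(
    origin: str, treatment: str, day: float, dyn: DynamicsConfig
) -> float:
    """Noiseless abundance multiplier for a species origin in one sample."""
    if origin == "litter":
        if treatment == "LO":
            return 1.0
        if treatment == "PL":
            return float(np.exp(-dyn.litter_decay * day))
        return 0.0
    if origin == "peat_native":
        return 0.0 if treatment == "LO" else 1.0
    if origin == "microbial_product":
        if treatment == "LO":
            return 0.0
        base = dyn.microbial_baseline
        if treatment == "PL":
            t = day / dyn.pulse_tau
            return base + dyn.pulse_amplitude * t * float(np.exp(1.0 - t))
        return base
    if origin == "peat_primed":
        if treatment == "LO":
            return 0.0
        if treatment == "PL":
            return float(np.exp(-dyn.primed_decay * day))
        return 1.0
    raise ValueError(f"unknown origin {origin!r}")


def generate_feature_table(
    species: list[MolecularSpecies],
    design: list[SampleDesign],
    dynamics: DynamicsConfig | None = None,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    emission_floor: float = 1e-4,
    p_nat: float = P_NATURAL_13C,
    mass_range: tuple[float, float] = (100.0, 1200.0),
) -> tuple[FeatureTable, TableGroundTruth]:
    """Render species into an LC-MS feature table plus its ground truth.

    One feature row is emitted per (species, isotopologue k) whose expected
    proportion — under either the labeled or the natural envelope — reaches
    ``emission_floor`` (detector dynamic range).  In labeled samples a
    species expresses its enrichment envelope; in unlabeled samples the
    natural-abundance envelope.  Unassigned noise rows are appended and
    recorded in the ground-truth map with an empty species id.
    """
    if not design:
        raise ValueError("design is empty")
    dyn = dynamics or DynamicsConfig()
    nz = noise or NoiseConfig()
    rng = np.random.default_rng(seed)

    sample_ids = [s.sample_id for s in design]
    n_samples = len(sample_ids)

    # noiseless species x sample abundances
    true_abund = np.empty((len(species), n_samples))
    for i, sp in enumerate(species):
        for j, s in enumerate(design):
            true_abund[i, j] = sp.base_abundance * _origin_multiplier(
                sp.origin, s.treatment, s.day, dyn
            )

    labeled_mask = np.array([s.label_status == "labeled" for s in design])

    masses, rts, snrs = [], [], []
    rows = []
    map_species, map_k = [], []
    for i, sp in enumerate(species):
        env_lab = expected_envelope(sp.n_carbon, sp.enrichment)
        env_nat = expected_envelope(sp.n_carbon, p_nat)
        k_set = np.nonzero(np.maximum(env_lab, env_nat) >= emission_floor)[0]
        props = np.where(labeled_mask[None, :], env_lab[k_set, None], env_nat[k_set, None])
        inten = true_abund[i][None, :] * props
        for idx, k in enumerate(k_set):
            mass_true = sp.neutral_mass + k * C13_MASS_DIFF
            ppm_err = rng.normal(0.0, nz.mass_ppm_sd)
            masses.append(mass_true * (1.0 + ppm_err * 1e-6))
            rts.append(max(0.0, sp.rt + rng.normal(0.0, nz.rt_jitter_sd)))
            snrs.append(float(rng.lognormal(np.log(30.0), 0.5)))
            rows.append(inten[idx])
            map_species.append(sp.species_id)
            map_k.append(int(k))

    n_signal = len(rows)
    n_noise = int(round(nz.noise_feature_fraction * n_signal))
    for _ in range(n_noise):
        masses.append(rng.uniform(mass_range[0], mass_range[1]))
        rts.append(rng.uniform(0.5, 70.0))
        snrs.append(float(rng.lognormal(np.log(3.0), 0.7)))
        present = rng.random(n_samples) < 0.3
        vals = rng.lognormal(np.log(1e7), 1.5, size=n_samples) * present
        rows.append(vals)
        map_species.append("")
        map_k.append(-1)

    inten = np.vstack(rows) if rows else np.empty((0, n_samples))
    # compound-level abundance noise: one factor per (species, sample),
    # shared by all isotopologues of that species in that sample
    sp_index = {sp.species_id: i for i, sp in enumerate(species)}
    species_idx = np.array([sp_index.get(s, -1) for s in map_species], dtype=int)
    if nz.intensity_cv > 0:
        sigma = np.sqrt(np.log1p(nz.intensity_cv**2))
        factors = rng.lognormal(-0.5 * sigma**2, sigma, size=(len(species), n_samples))
        sig_mask = species_idx >= 0
        inten[sig_mask] *= factors[species_idx[sig_mask]]
        n_noise_rows = int(np.count_nonzero(~sig_mask))
        if n_noise_rows:
            inten[~sig_mask] *= rng.lognormal(
                -0.5 * sigma**2, sigma, size=(n_noise_rows, n_samples)
            )
    # per-cell residual (within-spectrum) noise and dropout
    if nz.envelope_cv > 0:
        s2 = np.sqrt(np.log1p(nz.envelope_cv**2))
        inten = inten * rng.lognormal(-0.5 * s2**2, s2, size=inten.shape)
    if nz.missing_rate > 0:
        inten = inten * (rng.random(inten.shape) >= nz.missing_rate)
    if nz.detection_floor > 0:
        inten[inten < nz.detection_floor] = 0.0  # below limit of detection

    order = np.lexsort((np.asarray(rts), np.asarray(masses)))
    masses = np.asarray(masses)[order]
    rts = np.asarray(rts)[order]
    snrs = np.asarray(snrs)[order]
    inten = inten[order]
    map_species = [map_species[i] for i in order]
    map_k = [map_k[i] for i in order]

    # drop id collisions deterministically (same rounded mass and RT)
    ids_seen: set[str] = set()
    keep = []
    from .tables import format_feature_id

    for i in range(len(masses)):
        fid = format_feature_id(round(masses[i], 5), round(rts[i], 3))
        if fid in ids_seen:
            continue
        ids_seen.add(fid)
        keep.append(i)
    keep = np.asarray(keep, dtype=int)

    table = FeatureTable.from_arrays(
        masses[keep], rts[keep], snrs[keep], inten[keep], sample_ids
    )
    feature_map = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "species_id": [map_species[i] for i in keep],
            "k": [map_k[i] for i in keep],
        }
    )
    species_df = pd.DataFrame([asdict(sp) for sp in species])
    truth = TableGroundTruth(
        species=species_df,
        feature_map=feature_map,
        true_abundance=pd.DataFrame(
            true_abund, index=[sp.species_id for sp in species], columns=sample_ids
        ),
        labeled=pd.Series(
            {sp.species_id: sp.enrichment > p_nat + 1e-12 for sp in species}
        ),
        seed=seed,
    )
    return table, truth


# ----------------------------------------------------------------------
# NMR-style block
# ----------------------------------------------------------------------
def generate_nmr_block(
    n_metabolites: int,
    design: list[SampleDesign],
    labeled_fraction: float = 0.4,
    mass_range: tuple[float, float] = (32.0, 355.0),
    concentration_log_mean: float = np.log(0.1),
    concentration_log_sd: float = 1.0,
    cv: float = 0.2,
    dynamics: DynamicsConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Small-molecule concentration table sharing the incubation design.

    A ``labeled_fraction`` of metabolites is litter-derived (flagged True):
    abundant in litter-only samples and decaying in amended peat.  The rest
    are peat-derived and stable.  Returns the concentration table (columns:
    metabolite_id, neutral_mass, then one column per sample) and the boolean
    labeled flags indexed by metabolite id.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must be in [0, 1]")
    if mass_range[0] >= mass_range[1]:
        raise ValueError("empty mass range")
    dyn = dynamics or DynamicsConfig()
    rng = np.random.default_rng(seed)

    n_labeled = int(round(labeled_fraction * n_metabolites))
    ids = [f"nmr_{i:03d}" for i in range(n_metabolites)]
    flags = pd.Series(
        [i < n_labeled for i in range(n_metabolites)], index=ids, name="labeled"
    )
    masses = rng.uniform(mass_range[0], mass_range[1], size=n_metabolites)
    base = rng.lognormal(concentration_log_mean, concentration_log_sd, n_metabolites)

    conc = np.empty((n_metabolites, len(design)))
    for j, s in enumerate(design):
        for i in range(n_metabolites):
            origin = "litter" if flags.iloc[i] else "peat_native"
            conc[i, j] = base[i] * _origin_multiplier(origin, s.treatment, s.day, dyn)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        conc = conc * rng.lognormal(-0.5 * sigma**2, sigma, size=conc.shape)

    out = pd.DataFrame({"metabolite_id": ids, "neutral_mass": np.round(masses, 4)})
    out = pd.concat(
        [out, pd.DataFrame(conc, columns=[s.sample_id for s in design])], axis=1
    )
    return out, flags


# ----------------------------------------------------------------------
# Planted-effect blocks for discriminant benchmarking
# ----------------------------------------------------------------------
def generate_discriminant_blocks(
    n_samples_per_class: int = 12,
    n_features: tuple[int, int] = (200, 40),
    n_informative: tuple[int, int] = (20, 6),
    effect_size: float = 1.5,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.Series, dict[str, list[str]]]:
    """Two feature blocks with a planted PO/PL mean shift on known features.

    Informative features differ between classes by ``effect_size`` standard
    deviations (random sign per feature) on a unit-variance Gaussian
    background.  Returns ``(blocks, classes, informative_ids)`` with blocks
    oriented features x samples.
    """
    rng = np.random.default_rng(seed)
    classes = ["PO"] * n_samples_per_class + ["PL"] * n_samples_per_class
    sample_ids = [f"{c}-{i:02d}" for i, c in enumerate(classes)]
    class_vec = np.array([c == "PL" for c in classes], dtype=float)

    blocks: dict[str, pd.DataFrame] = {}
    informative: dict[str, list[str]] = {}
    for name, n_feat, n_inf in zip(("ms", "nmr"), n_features, n_informative):
        X = rng.standard_normal((n_feat, len(classes)))
        ids = [f"{name}_{i:03d}" for i in range(n_feat)]
        inf_idx = rng.choice(n_feat, size=n_inf, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_inf)
        for sign, i in zip(signs, inf_idx):
            X[i] += sign * effect_size * class_vec
        blocks[name] = pd.DataFrame(X, index=ids, columns=sample_ids)
        informative[name] = sorted(ids[i] for i in inf_idx)
    return blocks, pd.Series(classes, index=sample_ids, name="class"), informative


# ----------------------------------------------------------------------
# Flux series
# ----------------------------------------------------------------------
def simulate_flux_series(
    config: FluxConfig | None = None,
    seed: int | None = None,
):
    """Simulate jar CO2 flux observations plus their true decomposition.

    Unamended (PO) jars respire the peat baseline at the soil isotope ratio;
    amended (PL) jars add an exponentially decaying litter component at the
    litter ratio and a peat-derived priming pulse.  Observation noise is
    mean-one log-normal, applied to total flux and isotope ratio
    independently.  Returns ``(observations, ground_truth)`` where
    observations is a list of :class:`siampeat.flux.FluxObservation`.
    """
    from .flux import FluxObservation  # local import to avoid a cycle

    cfg = config or FluxConfig()
    if cfg.litter_l0 > 0 and abs(cfg.r_litter - cfg.r_soil) < 1e-12:
        raise ValueError(
            "r_litter equals r_soil with a nonzero litter component: "
            "the mixture is unidentifiable by construction"
        )
    rng = np.random.default_rng(seed)

    obs: list[FluxObservation] = []
    truth_rows = []
    sigma = np.sqrt(np.log1p(cfg.cv**2)) if cfg.cv > 0 else 0.0
    for treatment in ("PO", "PL"):
        for jar in range(1, cfg.n_jars + 1):
            jar_id = f"{treatment}-{jar}"
            label = "labeled" if treatment == "PL" else "unlabeled"
            for day in cfg.days:
                litter = (
                    cfg.litter_l0 * float(np.exp(-cfg.litter_decay * day))
                    if treatment == "PL"
                    else 0.0
                )
                priming = (
                    cfg.priming_amplitude * day * float(np.exp(-day / cfg.priming_tau))
                    if treatment == "PL"
                    else 0.0
                )
                peat = cfg.baseline + priming
                f_net = litter + peat
                r_net = (litter * cfg.r_litter + peat * cfg.r_soil) / f_net
                truth_rows.append(
                    {
                        "jar_id": jar_id,
                        "treatment": treatment,
                        "day": day,
                        "litter": litter,
                        "peat": peat,
                        "priming": priming,
                        "f_net": f_net,
                        "r_net": r_net,
                    }
                )
                if sigma > 0:
                    f_obs = f_net * rng.lognormal(-0.5 * sigma**2, sigma)
                    r_obs = float(
                        np.clip(r_net * rng.lognormal(-0.5 * sigma**2, sigma), 0.0, 1.0)
                    )
                else:
                    f_obs, r_obs = f_net, r_net
                obs.append(
                    FluxObservation(
                        jar_id=jar_id,
                        treatment=treatment,
                        label_status=label,
                        day=float(day),
                        f_net=float(f_obs),
                        r_net=float(r_obs),
                    )
                )
    truth = FluxGroundTruth(
        components=pd.DataFrame(truth_rows), config=asdict(cfg), seed=seed
    )
    return obs, truth
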
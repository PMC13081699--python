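"""Synthetic cohorts, parcellations, and functional-connectivity matrices.

Emulates a developmental reading cohort: ages 6-21 skewed toward
childhood, three reading groups defined by TOWRE composite cutoffs
(poor < 91, typical 91-109, exceptional > 109), covariates with
realistic group-level summaries, and Fisher-z connectivity whose
within-network strength (Default and Control networks especially)
increases with age while Default<->Control coupling grows more
negative. A configurable "maturational lag" shifts the effective age
of each reading group (poor readers -delta, exceptional +delta) on a
chosen edge scope, planting the group bias the downstream brain-age
analysis is designed to detect.

Everything is a pure function of its configuration and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import NETWORKS7, canonical_edges, edge_subset_mask

GROUPS = ("PR", "TR", "ER")

#: TOWRE cutoffs on the composite index (mean of PDE and SWE standard scores)
TOWRE_PR_MAX = 91.0   # poor reader: index < 91
TOWRE_ER_MIN = 109.0  # exceptional reader: index > 109

#: TOWRE subtest (mean, sd) per group: Phonemic Decoding and Sight Word Efficiency
TOWRE_PARAMS = {
    "ER": {"pde": (118.0, 8.4), "swe": (123.8, 8.6)},
    "TR": {"pde": (98.4, 7.6), "swe": (100.7, 7.8)},
    "PR": {"pde": (76.1, 9.3), "swe": (77.5, 10.0)},
}
TOWRE_SCORE_RANGE = (55.0, 145.0)  # standard-score floor/ceiling

#: covariate summaries per group
GENDER_PCT_FEMALE = {"ER": 29.5, "TR": 36.7, "PR": 34.6}
SES_PARAMS = {"ER": (9.0, 3.0), "TR": (8.5, 3.1), "PR": (6.8, 3.7)}
PIQ_PARAMS = {"ER": (11.6, 3.1), "TR": (10.3, 3.2), "PR": (8.9, 2.9)}
HANDEDNESS_PCT_RIGHT = {"ER": 91.7, "TR": 86.7, "PR": 91.0}
#: fraction of missing entries (emulating incomplete phenotyping)
SES_MISSING_RATE = {"ER": 0.140, "TR": 0.172, "PR": 0.251}
PIQ_MISSING_RATE = {"ER": 0.0, "TR": 0.0, "PR": 0.156}

#: relative spatial extent of the seven canonical networks (Default and
#: Control largest, as in cortical parcellations)
NETWORK_WEIGHTS7 = (0.11, 0.14, 0.10, 0.10, 0.07, 0.21, 0.27)

MAX_RESAMPLES = 1000


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``maturational_lag_years`` is the per-group shift of effective age
    (PR -delta, TR 0, ER +delta) applied on ``lag_scope`` edges;
    ``age_slope_z_per_year`` the developmental slope of connectivity on
    developmental edges; ``frac_developmental_edges`` the fraction of all
    edges carrying an age slope; ``edge_noise_sd`` i.i.d. Gaussian noise
    per edge and participant, in z units.
    """

    n_participants: int = 742
    group_proportions: tuple[float, float, float] = (211 / 742, 338 / 742, 193 / 742)  # PR, TR, ER
    age_range: tuple[float, float] = (6.0, 21.0)
    maturational_lag_years: float = 0.0
    lag_scope: str = "reading_network_edges"  # or "all_edges"
    n_roi: int = 400
    n_networks: int = 7
    frac_developmental_edges: float = 0.10
    age_slope_z_per_year: float = 0.02
    edge_noise_sd: float = 0.10
    #: skew-normal (shape, loc, scale) for ages, truncated to age_range;
    #: the default peaks near 8-9 years and tails into adolescence
    age_skewnorm: tuple[float, float, float] = (3.0, 7.5, 4.5)
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.group_proportions, dtype=float)
        if props.size != 3 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("group_proportions must be 3 nonnegative reals summing to 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if self.edge_noise_sd < 0:
            raise ValueError("edge_noise_sd must be >= 0")
        if self.lag_scope not in ("reading_network_edges", "all_edges"):
            raise ValueError(f"unknown lag_scope {self.lag_scope!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticFCSet:
    """Per-participant Fisher-z edge vectors with the planted generative model."""

    edges: np.ndarray            # (M, 2) canonical edge order
    baseline_z: np.ndarray       # (M,)
    age_slope_z: np.ndarray      # (M,) true slope per edge
    X: np.ndarray                # (n_participants, M)
    participant_ids: list = field(default_factory=list)
    age_ref: float = 0.0

    @property
    def developmental_mask(self) -> np.ndarray:
        return self.age_slope_z != 0.0


def assign_reading_group(towre_index: float) -> str:
    """Reading group from the TOWRE composite: <91 PR, 91-109 TR, >109 ER."""
    if not np.isfinite(towre_index):
        raise ValueError("towre_index must be finite")
    if towre_index < TOWRE_PR_MAX:
        return "PR"
    if towre_index <= TOWRE_ER_MIN:
        return "TR"
    return "ER"


def largest_remainder(n: int, proportions) -> np.ndarray:
    """Apportion ``n`` seats to proportions by the largest-remainder method."""
    props = np.asarray(proportions, dtype=float)
    quotas = n * props / props.sum()
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # ties broken by position, stable
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_ages(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    shape, loc, scale = config.age_skewnorm
    lo, hi = config.age_range
    out = np.empty(0)
    while out.size < n:
        draw = stats.skewnorm.rvs(shape, loc=loc, scale=scale,
                                  size=2 * (n - out.size) + 16, random_state=rng)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def _group_cutoff_ok(group: str, index: np.ndarray) -> np.ndarray:
    if group == "PR":
        return index < TOWRE_PR_MAX
    if group == "TR":
        return (index >= TOWRE_PR_MAX) & (index <= TOWRE_ER_MIN)
    return index > TOWRE_ER_MIN


def _sample_towre(rng: np.random.Generator, group: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-normal subtest scores resampled until the composite obeys the cutoff."""
    (pde_m, pde_s) = TOWRE_PARAMS[group]["pde"]
    (swe_m, swe_s) = TOWRE_PARAMS[group]["swe"]
    lo, hi = TOWRE_SCORE_RANGE
    pde = np.full(n, np.nan)
    swe = np.full(n, np.nan)
    todo = np.arange(n)
    for _ in range(MAX_RESAMPLES):
        if todo.size == 0:
            break
        cand_pde = _truncnorm(rng, pde_m, pde_s, lo, hi, todo.size)
        cand_swe = _truncnorm(rng, swe_m, swe_s, lo, hi, todo.size)
        ok = _group_cutoff_ok(group, (cand_pde + cand_swe) / 2.0)
        pde[todo[ok]] = cand_pde[ok]
        swe[todo[ok]] = cand_swe[ok]
        todo = todo[~ok]
    if todo.size:
        raise RuntimeError(
            f"could not satisfy the TOWRE cutoff for group {group} "
            f"after {MAX_RESAMPLES} resamples"
        )
    return pde, swe


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort table: ids, ages, TOWRE scores, groups, covariates.

    Group sizes follow largest-remainder apportionment of
    ``n_participants`` by ``group_proportions`` (PR, TR, ER order);
    subtest scores are truncated normals resampled until each
    participant's composite satisfies their group cutoff. SES and PIQ
    carry missing entries at group-specific rates.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    sizes = largest_remainder(config.n_participants, config.group_proportions)
    rows = []
    for group, n_g in zip(GROUPS, sizes):
        if n_g == 0:
            continue
        ages = _sample_ages(rng, n_g, config)
        pde, swe = _sample_towre(rng, group, n_g)
        ses = np.round(_truncnorm(rng, *SES_PARAMS[group], 1.0, 18.0, n_g))
        piq = np.round(_truncnorm(rng, *PIQ_PARAMS[group], 1.0, 19.0, n_g))
        ses[rng.random(n_g) < SES_MISSING_RATE[group]] = np.nan
        piq[rng.random(n_g) < PIQ_MISSING_RATE[group]] = np.nan
        gender = np.where(rng.random(n_g) < GENDER_PCT_FEMALE[group] / 100.0, "F", "M")
        hand = np.where(rng.random(n_g) < HANDEDNESS_PCT_RIGHT[group] / 100.0, "R", "L")
        rows.append(pd.DataFrame({
            "age": ages, "towre_pde": pde, "towre_swe": swe,
            "group": group, "gender": gender, "ses": ses,
            "piq": piq, "handedness": hand,
        }))
    cohort = pd.concat(rows, ignore_index=True)
    cohort["towre_index"] = (cohort["towre_pde"] + cohort["towre_swe"]) / 2.0
    cohort.insert(0, "participant", [f"sub-{i:04d}" for i in range(len(cohort))])
    return cohort


def generate_parcellation(n_roi: int = 400, n_networks: int = 7,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic cortical parcellation: ids, names, networks, hemispheres, centroids.

    ROIs split evenly L/R (ids 0..n/2-1 left); network sizes follow fixed
    unequal proportions with Default and Control largest; centroids are
    sampled in a brain-sized box with the x sign set by hemisphere.
    """
    if n_roi % 2:
        raise ValueError("n_roi must be even (split across hemispheres)")
    if not 1 <= n_networks <= n_roi:
        raise ValueError("need n_roi >= n_networks >= 1")
    rng = np.random.default_rng([int(seed), 1])
    if n_networks <= len(NETWORKS7):
        labels = NETWORKS7[:n_networks]
        weights = np.asarray(NETWORK_WEIGHTS7[:n_networks])
    else:
        labels = NETWORKS7 + tuple(f"Net{k}" for k in range(8, n_networks + 1))
        weights = np.concatenate([NETWORK_WEIGHTS7,
                                  np.full(n_networks - 7, min(NETWORK_WEIGHTS7))])
    sizes = largest_remainder(n_roi, weights / weights.sum())
    if np.any(sizes == 0):  # tiny parcellations: guarantee every network a seat
        sizes = np.maximum(sizes, 1)
        while sizes.sum() > n_roi:
            sizes[np.argmax(sizes)] -= 1

    # split each network across hemispheres; odd remainders alternate sides
    left_sizes = sizes // 2
    odd = np.flatnonzero(sizes % 2)
    for pos, k in enumerate(odd):
        if pos % 2 == 0:
            left_sizes[k] += 1
    # balance to exactly n/2 per hemisphere
    while left_sizes.sum() > n_roi // 2:
        left_sizes[np.argmax(left_sizes)] -= 1
    while left_sizes.sum() < n_roi // 2:
        k = int(np.argmax(sizes - left_sizes))
        left_sizes[k] += 1

    networks, hemis = [], []
    for hemi, hemi_sizes in (("L", left_sizes), ("R", sizes - left_sizes)):
        for label, m in zip(labels, hemi_sizes):
            networks.extend([label] * int(m))
            hemis.extend([hemi] * int(m))
    hemis = np.asarray(hemis)
    x = rng.uniform(8.0, 68.0, n_roi) * np.where(hemis == "L", -1.0, 1.0)
    y = rng.uniform(-104.0, 70.0, n_roi)
    z = rng.uniform(-44.0, 76.0, n_roi)
    idx_within = pd.Series(networks).groupby(networks).cumcount() + 1
    names = [f"{h}_{net}_{k}" for h, net, k in zip(hemis, networks, idx_within)]
    return pd.DataFrame({
        "roi": np.arange(n_roi), "name": names, "network": networks,
        "hemisphere": hemis, "x": x, "y": y, "z": z,
    })


def generate_coordinates(parcellation: pd.DataFrame, n_coords: int = 416,
                         n_out_of_range: int = 49, seed: int = 0,
                         jitter_mm: float = 4.0, zipf_a: float = 1.3) -> pd.DataFrame:
    """Synthetic meta-analysis coordinate list (x, y, z in mm).

    In-range coordinates cluster near centroids of a "reading network":
    ROIs drawn preferentially from the Default, Control, and
    Salience/Ventral-Attention networks with a left-hemisphere bias, with
    Zipf-distributed multiplicity so that hit-count cutoffs produce a
    nested ladder of ROI sets. Out-of-range coordinates fall far outside
    the centroid box (emulating subcortical/cerebellar foci).
    """
    if n_out_of_range > n_coords:
        raise ValueError("n_out_of_range cannot exceed n_coords")
    rng = np.random.default_rng([int(seed), 2])
    pref_networks = {"Default": 3.0, "Cont": 3.0, "SalVentAttn": 2.0}
    w = parcellation["network"].map(pref_networks).fillna(0.3).to_numpy()
    w = w * np.where(parcellation["hemisphere"].to_numpy() == "L", 2.0, 1.0)
    # Zipf-like per-ROI propensity creates the multiplicity ladder
    ranks = rng.permutation(len(parcellation)) + 1
    w = w * ranks ** (-zipf_a)
    w /= w.sum()
    n_in = n_coords - n_out_of_range
    rois = rng.choice(len(parcellation), size=n_in, p=w)
    cent = parcellation.loc[rois, ["x", "y", "z"]].to_numpy()
    coords_in = cent + rng.uniform(-jitter_mm, jitter_mm, size=(n_in, 3))
    # far-field points: well below the sampled z range
    coords_out = np.column_stack([
        rng.uniform(-30.0, 30.0, n_out_of_range),
        rng.uniform(-60.0, 10.0, n_out_of_range),
        rng.uniform(-220.0, -160.0, n_out_of_range),
    ])
    coords = np.vstack([coords_in, coords_out])
    order = rng.permutation(n_coords)
    return pd.DataFrame(coords[order], columns=["x", "y", "z"])


def simulate_fc(cohort: pd.DataFrame, parcellation: pd.DataFrame,
                config: SimulationConfig,
                reading_rois=None) -> SyntheticFCSet:
    """Per-participant Fisher-z edge vectors with planted developmental structure.

    ``z(e, p) = baseline(e) + slope(e) * (effective_age(p, e) - age_ref) + noise``
    where a fraction ``frac_developmental_edges`` of edges get nonzero
    slopes: within-network Default/Control edges strengthen
    (+``age_slope_z_per_year``), Default<->Control edges deepen their
    anticorrelation (-slope), and any remainder are random edges with
    half-magnitude slopes of random sign. Reading-group lag shifts
    effective age by -delta (PR) / +delta (ER) on ``lag_scope`` edges.
    """
    n_roi = len(parcellation)
    if n_roi != config.n_roi:
        raise ValueError("parcellation size does not match config.n_roi")
    rng = np.random.default_rng([int(config.seed), 3])
    edges = canonical_edges(parcellation["roi"].to_numpy())
    M = edges.shape[0]
    net = parcellation.set_index("roi")["network"]
    net_i = net.loc[edges[:, 0]].to_numpy()
    net_j = net.loc[edges[:, 1]].to_numpy()
    within = net_i == net_j

    baseline = np.where(within, 0.30, 0.08) + rng.normal(0.0, 0.05, M)

    slope = np.zeros(M)
    n_dev = int(round(config.frac_developmental_edges * M))
    core_pos = np.flatnonzero(within & np.isin(net_i, ("Default", "Cont")))
    core_neg = np.flatnonzero(
        (~within)
        & (np.isin(net_i, ("Default", "Cont")) & np.isin(net_j, ("Default", "Cont")))
    )
    take_pos = core_pos if core_pos.size <= n_dev else rng.choice(core_pos, n_dev, replace=False)
    budget = n_dev - take_pos.size
    take_neg = core_neg[:0]
    if budget > 0:
        take_neg = core_neg if core_neg.size <= budget else rng.choice(core_neg, budget, replace=False)
        budget -= take_neg.size
    slope[take_pos] = config.age_slope_z_per_year
    slope[take_neg] = -config.age_slope_z_per_year
    if budget > 0:
        rest = np.setdiff1d(np.arange(M), np.concatenate([take_pos, take_neg]))
        extra = rng.choice(rest, min(budget, rest.size), replace=False)
        slope[extra] = rng.choice([-0.5, 0.5], extra.size) * config.age_slope_z_per_year

    if config.lag_scope == "all_edges":
        lag_mask = np.ones(M, dtype=bool)
    else:
        if reading_rois is None:
            if config.maturational_lag_years != 0.0:
                raise ValueError(
                    "lag_scope='reading_network_edges' with a nonzero lag "
                    "requires an explicit reading_rois set"
                )
            lag_mask = np.zeros(M, dtype=bool)
        else:
            lag_mask = edge_subset_mask(edges, reading_rois,
                                        valid_ids=parcellation["roi"].to_numpy())

    age_ref = float(np.mean(config.age_range))
    delta = float(config.maturational_lag_years)
    group_shift = cohort["group"].map({"PR": -delta, "TR": 0.0, "ER": delta}).to_numpy()
    ages = cohort["age"].to_numpy(dtype=float)

    n = len(cohort)
    centered = ages - age_ref
    X = baseline[None, :] + np.outer(centered, slope)
    if delta != 0.0:
        X[:, lag_mask] += np.outer(group_shift, slope[lag_mask])
    if config.edge_noise_sd > 0:
        X += rng.normal(0.0, config.edge_noise_sd, size=(n, M))
    return SyntheticFCSet(
        edges=edges, baseline_z=baseline, age_slope_z=slope, X=X,
        participant_ids=cohort["participant"].tolist(), age_ref=age_ref,
    )


def simulate_dataset(config: SimulationConfig,
                     coord_kwargs: dict | None = None,
                     cutoff_ks: tuple[int, ...] = (0, 1, 2, 4),
                     radius_mm: float = 12.0):
    """End-to-end synthetic study: cohort, parcellation, coordinates, FC, ROI sets.

    The reading-network ROI ladder is derived from the synthetic
    coordinate list exactly as in the real analysis (nearest-centroid
    mapping, hit counts, minimum-count cutoffs); the k>=1 set defines the
    maturational-lag scope when ``lag_scope='reading_network_edges'``.
    Returns ``(cohort, parcellation, fc_set, roi_sets)`` with ``roi_sets``
    keyed by cutoff k.
    """
    from .reading_map import count_hits, apply_cutoff

    cohort = simulate_cohort(config)
    parcellation = generate_parcellation(config.n_roi, config.n_networks, config.seed)
    coords = generate_coordinates(parcellation, seed=config.seed,
                                  **(coord_kwargs or {}))
    hits = count_hits(coords, parcellation, radius=radius_mm)
    roi_sets = {k: apply_cutoff(hits, k) for k in cutoff_ks}
    reading = roi_sets.get(1)
    if reading is None:
        reading = apply_cutoff(hits, 1)
    fc = simulate_fc(cohort, parcellation, config, reading_rois=reading)
    return cohort, parcellation, fc, roi_sets
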
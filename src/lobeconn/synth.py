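"""In-silico cohort generator.

Emulates the data structure of a longitudinal resting-state study of two
surgical-outcome groups (seizure-free SF vs non-seizure-free NSF) scanned
before and after an anterior temporal lobectomy:

* a bilateral parcellation whose regions belong to a small number of
  functional modules, with a homotopic partner for every region;
* per subject-session band-limited regional time series drawn from a
  module-factor covariance model (positive semi-definite by construction);
* planted effects with a known ground truth — an outcome x treatment
  connectivity interaction on designated edges, outcome-dependent hub
  redundancy, and a post-operative degradation of modular structure coupled
  to the surgical damage of each subject;
* lesion profiles (per-ROI damage fractions restricted to a designated
  "temporal" subset) and resection-cavity volumes on the scale reported for
  real lobectomy series (about 5 +/- 2 cm^3).

Covariance model
----------------
Each region i loads on its module factor (loading sqrt(rho_within)) and on a
weak global factor (loading sqrt(rho_between)); the global factor is largely
removed again by global-signal regression downstream, which is realistic.
Between-module integration is carried by designated "connector" regions with
*cross-loadings* on a neighbouring module's factor, arranged in a ring over
modules: the primary connector pair of module m also loads on module m+1's
factor (loading sqrt(rho_connector)), the secondary pair on module m-1's
factor at a reduced base scale.  Cross-module shortest paths therefore route
through connectors, which acquire high betweenness; because the mechanism
lives in the module factors, it survives global-signal regression.  The
population correlation matrix is Lambda Lambda' + Psi with unit diagonal,
hence PSD by construction.  Planted effects act on the loadings:

* NSF subjects scale the *secondary* connector cross-loadings by
  ``hub_concentration_factor``, adding a second, reverse-direction set of
  strong hub-mediated connections.  Under proportional cost thresholding the
  edge budget is fixed, so these strong hub edges crowd distributed
  within-module edges out of the NSF network: its connectivity concentrates
  on hubs, and targeted hub removal fragments it earlier.  The SF network,
  whose budget stays spread over module lattices, is relatively redundant
  and degrades more slowly — the planted resilience contrast;
* SF post sessions add a dedicated pair factor with loading sqrt(delta) on
  each planted interaction edge, shifting that edge's correlation by +delta;
* post sessions scale all structural loadings by
  sqrt(1 - damage_attenuation * burden), where burden is the subject's summed
  damage fraction over the lesion-eligible set — heavier resections leave a
  less modular (less "regular") post-operative network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, LesionProfile, Parcellation, RoiTimeSeries, SubjectRecord, POST, PRE

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "make_parcellation",
    "connector_pairs",
    "default_lesion_roi_set",
    "default_interaction_edges",
    "build_population_covariance",
    "implied_correlation",
    "simulate_cohort",
    "make_lesion_volumes",
]


class ConfigError(ValueError):
    """A generator configuration requests an unreachable covariance."""


def make_parcellation(n_rois: int = 110, n_modules: int = 6) -> Parcellation:
    """Build a balanced bilateral parcellation.

    Left-hemisphere regions get ids ``0..n_rois/2-1``, right-hemisphere ids
    ``n_rois/2..n_rois-1``; ``partner(i) = i +/- n_rois/2``.  Homotopic pairs
    are assigned to ``n_modules`` contiguous, near-equal module blocks, so
    partners always share a module.  Deterministic for given arguments.
    """
    if n_rois % 2 != 0:
        raise ValueError(f"n_rois must be even, got {n_rois}")
    n_pairs = n_rois // 2
    if n_modules < 1 or n_modules > n_pairs:
        raise ValueError(f"n_modules must be in 1..{n_pairs}, got {n_modules}")
    pair_module = (np.arange(n_pairs) * n_modules) // n_pairs + 1
    names = [f"ROI{p + 1:03d}.L" for p in range(n_pairs)] + [
        f"ROI{p + 1:03d}.R" for p in range(n_pairs)
    ]
    hemisphere = np.array(["L"] * n_pairs + ["R"] * n_pairs, dtype="U1")
    module_id = np.concatenate([pair_module, pair_module])
    partner = np.concatenate([np.arange(n_pairs) + n_pairs, np.arange(n_pairs)])
    return Parcellation(tuple(names), hemisphere, module_id, partner)


def connector_pairs(parcellation: Parcellation) -> dict[int, tuple[int, int | None]]:
    """Primary and secondary connector *pair indices* per module.

    The first homotopic pair of each module is the primary connector, the
    second (when the module has one) the secondary.  Both nodes of a pair are
    connectors.
    """
    n_pairs = parcellation.n_rois // 2
    pair_module = parcellation.module_id[:n_pairs]
    out: dict[int, tuple[int, int | None]] = {}
    for m in np.unique(pair_module):
        pairs = np.flatnonzero(pair_module == m)
        out[int(m)] = (int(pairs[0]), int(pairs[1]) if len(pairs) > 1 else None)
    return out


def _connector_nodes(parcellation: Parcellation) -> tuple[set[int], set[int]]:
    """(primary, secondary) connector node ids, both hemispheres."""
    n_pairs = parcellation.n_rois // 2
    primary: set[int] = set()
    secondary: set[int] = set()
    for _, (p, s) in connector_pairs(parcellation).items():
        primary.update((p, p + n_pairs))
        if s is not None:
            secondary.update((s, s + n_pairs))
    return primary, secondary


def default_lesion_roi_set(parcellation: Parcellation, size: int = 14) -> tuple[int, ...]:
    """Left-hemisphere, non-connector regions of the lowest-numbered modules.

    Stands in for the anterior/mesial temporal structures removed by a left
    lobectomy (right-lateralised subjects are mirrored onto this set).
    """
    primary, secondary = _connector_nodes(parcellation)
    connectors = primary | secondary
    order = np.argsort(parcellation.module_id, kind="stable")
    left = [int(i) for i in order if parcellation.hemisphere[i] == "L"]
    # prefer non-connector regions; fall back to connectors on tiny parcellations
    chosen = [i for i in left if i not in connectors][:size]
    if len(chosen) < size:
        chosen += [i for i in left if i in connectors][: size - len(chosen)]
    if len(chosen) < size:
        raise ValueError(f"parcellation too small for a lesion set of {size} ROIs")
    return tuple(chosen)


def default_interaction_edges(parcellation: Parcellation) -> tuple[tuple[int, int], ...]:
    """Two homotopic cross-module edges far from the lesion set.

    Mirrors the bilateral pair of significant edges the analysis is meant to
    recover: one left-hemisphere edge between the last two modules and its
    right-hemisphere mirror.
    """
    primary, secondary = _connector_nodes(parcellation)
    connectors = primary | secondary
    n_pairs = parcellation.n_rois // 2
    modules = np.unique(parcellation.module_id)
    if len(modules) < 2:
        # single-module parcellation: use the last two eligible pairs
        eligible = [i for i in range(n_pairs) if i not in connectors]
        a, b = eligible[-2], eligible[-1]
    else:
        m_a, m_b = modules[-2], modules[-1]
        pick = {}
        for m in (m_a, m_b):
            in_module = [i for i in range(n_pairs) if parcellation.module_id[i] == m]
            cand = [i for i in in_module if i not in connectors] or in_module
            pick[m] = cand[-1]
        a, b = pick[m_a], pick[m_b]
    return ((a, b), (a + n_pairs, b + n_pairs))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Group sizes, scan length and repetition time copy the emulated study
    design (23/14 subjects scanned pre-operatively, of whom 14/10 return
    post-operatively; 250 retained volumes at TR = 2 s).  Effect sizes are
    generator parameters with no empirical counterpart; defaults are chosen
    so the planted contrasts are detectable at these sample sizes.
    """

    n_rois: int = 110
    n_modules: int = 6
    n_timepoints: int = 250
    tr_seconds: float = 2.0
    n_sf_pre: int = 23
    n_nsf_pre: int = 14
    n_sf_post: int = 14
    n_nsf_post: int = 10
    rho_within_module: float = 0.30
    rho_between_module: float = 0.05
    rho_connector: float = 0.45
    secondary_connector_scale: float = 1.0 / 3.0
    hub_concentration_factor: float = 3.0
    interaction_edges: tuple[tuple[int, int], ...] | None = None
    interaction_delta: float = 0.60
    ar_coeff: float = 0.3
    subject_jitter_sd: float = 0.04
    nuisance_coupling: float = 0.25
    lesion_roi_set: tuple[int, ...] | None = None
    n_damaged_range: tuple[int, int] = (3, 6)
    lesion_beta: tuple[float, float] = (2.0, 2.0)
    lesion_signal_loss: float = 0.8
    damage_attenuation: float = 2.0
    lacuna_volume_mean_cm3: float = 5.0
    lacuna_volume_sd_cm3: float = 1.8
    lacuna_volume_min_cm3: float = 1.0
    rng_seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        if self.n_rois % 2 != 0:
            errors.append("n_rois must be even")
        if self.n_timepoints < 32:
            errors.append("n_timepoints must be >= 32")
        if not 0 < self.tr_seconds:
            errors.append("tr_seconds must be positive")
        for name in ("rho_within_module", "rho_between_module", "rho_connector", "interaction_delta"):
            v = getattr(self, name)
            if not -1 < v < 1:
                errors.append(f"{name} must lie in (-1, 1)")
        if self.secondary_connector_scale <= 0:
            errors.append("secondary_connector_scale must be positive")
        if self.hub_concentration_factor < 1:
            errors.append("hub_concentration_factor must be >= 1")
        if self.n_sf_post > self.n_sf_pre or self.n_nsf_post > self.n_nsf_pre:
            errors.append("post group sizes cannot exceed pre group sizes")
        if not 0 <= self.ar_coeff < 1:
            errors.append("ar_coeff must lie in [0, 1)")
        lo, hi = self.n_damaged_range
        if not 1 <= lo <= hi:
            errors.append("n_damaged_range must satisfy 1 <= lo <= hi")
        return errors

    def resolved(self) -> "GeneratorConfig":
        """Fill in parcellation-dependent defaults (lesion set, planted edges)."""
        errors = self.validate()
        if errors:
            raise ConfigError("; ".join(errors))
        parc = make_parcellation(self.n_rois, self.n_modules)
        updates: dict = {}
        if self.lesion_roi_set is None:
            size = min(14, self.n_rois // 2 - 2 * len(np.unique(parc.module_id)))
            size = max(size, self.n_damaged_range[1])
            updates["lesion_roi_set"] = default_lesion_roi_set(parc, size)
        if self.interaction_edges is None:
            updates["interaction_edges"] = default_interaction_edges(parc)
        return dataclasses.replace(self, **updates) if updates else self


def _loadings(
    config: GeneratorConfig,
    parcellation: Parcellation,
    outcome: str,
    session: str,
    damage_fractions: np.ndarray | None = None,
) -> np.ndarray:
    """Factor-loading matrix Lambda (N x K) for one group cell.

    Columns: one factor per module, one weak global factor, and (for SF post
    sessions) one pair factor per planted interaction edge.  Connector pairs
    carry ring cross-loadings onto the neighbouring module's factor.
    """
    n = parcellation.n_rois
    n_pairs = n // 2
    modules = np.unique(parcellation.module_id)
    n_modules = len(modules)
    edges = config.interaction_edges or ()
    lam = np.zeros((n, n_modules + 1 + len(edges)))

    a_within = np.sqrt(config.rho_within_module)
    col_of = {int(m): k for k, m in enumerate(modules)}
    for m, k in col_of.items():
        lam[parcellation.module_id == m, k] = a_within

    if n_modules > 1:
        a_cross = np.sqrt(config.rho_connector)
        sec_scale = config.secondary_connector_scale * (
            config.hub_concentration_factor if outcome == "NSF" else 1.0
        )
        conn = connector_pairs(parcellation)
        mods = sorted(conn)
        for idx, m in enumerate(mods):
            nxt = mods[(idx + 1) % len(mods)]
            prv = mods[(idx - 1) % len(mods)]
            p_pair, s_pair = conn[m]
            for node in (p_pair, p_pair + n_pairs):
                lam[node, col_of[nxt]] = a_cross
            if s_pair is not None:
                for node in (s_pair, s_pair + n_pairs):
                    lam[node, col_of[prv]] = a_cross * sec_scale

    lam[:, n_modules] = np.sqrt(config.rho_between_module)

    if damage_fractions is not None:
        burden = float(np.sum(damage_fractions)) / max(len(config.lesion_roi_set or ()), 1)
        scale = np.sqrt(max(1.0 - config.damage_attenuation * burden, 0.05))
        lam *= scale
        node_scale = np.sqrt(1.0 - config.lesion_signal_loss * np.asarray(damage_fractions))
        lam *= node_scale[:, None]

    if outcome == "SF" and session == POST:
        for e, (i, j) in enumerate(edges):
            lam[i, n_modules + 1 + e] = np.sqrt(config.interaction_delta)
            lam[j, n_modules + 1 + e] = np.sqrt(config.interaction_delta)
    return lam


def build_population_covariance(
    config: GeneratorConfig,
    parcellation: Parcellation | None = None,
    outcome: str = "SF",
    session: str = PRE,
    damage_fractions: np.ndarray | None = None,
) -> np.ndarray:
    """Population correlation matrix for one outcome x session cell.

    ``Lambda Lambda' + Psi`` with a unit diagonal; PSD by construction.
    Raises :class:`ConfigError` naming the offending region if the requested
    loadings leave no room for idiosyncratic variance.
    """
    config = config.resolved()
    if parcellation is None:
        parcellation = make_parcellation(config.n_rois, config.n_modules)
    lam = _loadings(config, parcellation, outcome, session, damage_fractions)
    communality = np.sum(lam**2, axis=1)
    bad = np.flatnonzero(communality >= 1.0)
    if bad.size:
        i = int(bad[0])
        raise ConfigError(
            f"requested correlations unreachable: ROI {parcellation.names[i]} "
            f"(id {i}) has communality {communality[i]:.3f} >= 1"
        )
    sigma = lam @ lam.T
    np.fill_diagonal(sigma, 1.0)
    return sigma


def implied_correlation(
    config: GeneratorConfig,
    i: int,
    j: int,
    outcome: str = "SF",
    session: str = PRE,
    parcellation: Parcellation | None = None,
    damage_fractions: np.ndarray | None = None,
) -> float:
    """Analytic population correlation of one edge (sum of loading products)."""
    config = config.resolved()
    if parcellation is None:
        parcellation = make_parcellation(config.n_rois, config.n_modules)
    lam = _loadings(config, parcellation, outcome, session, damage_fractions)
    return float(lam[i] @ lam[j])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lo:
            return float(x)
    return lo


def _ar1_innovations(rng: np.random.Generator, t: int, n: int, phi: float) -> np.ndarray:
    """T x N unit-variance AR(1) innovations (stationary start)."""
    eta = rng.standard_normal((t, n))
    if phi == 0:
        return eta
    out = np.empty_like(eta)
    out[0] = eta[0]
    c = np.sqrt(1.0 - phi**2)
    for k in range(1, t):
        out[k] = phi * out[k - 1] + c * eta[k]
    return out


def _smooth_series(rng: np.random.Generator, t: int, n: int, phi: float = 0.9) -> np.ndarray:
    x = _ar1_innovations(rng, t, n, phi)
    return (x - x.mean(axis=0)) / x.std(axis=0)


def simulate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw a full cohort: subjects, lesions, time series, motion, nuisance.

    Deterministic for a fixed config (seed included): identical configs give
    byte-identical cohorts.
    """
    config = (config or GeneratorConfig()).resolved()
    rng = np.random.default_rng(config.rng_seed)
    parc = make_parcellation(config.n_rois, config.n_modules)
    cohort = Cohort(parcellation=parc, subjects=[])

    n_pairs = config.n_rois // 2
    lesion_set = np.asarray(config.lesion_roi_set, dtype=int)

    specs = [("SF", config.n_sf_pre, config.n_sf_post), ("NSF", config.n_nsf_pre, config.n_nsf_post)]
    counter = 0
    for outcome, n_pre, n_post in specs:
        for k in range(n_pre):
            counter += 1
            sid = f"P{counter:03d}"
            sessions = (PRE, POST) if k < n_post else (PRE,)
            laterality = "L" if k % 2 == 0 else "R"
            onset = _truncated_normal(rng, 13.0, 6.0, 1.0)
            duration = _truncated_normal(rng, 12.0, 6.0, 1.0)
            sex = "M" if rng.random() < 0.55 else "F"
            jitter = 1.0 + rng.normal(0.0, config.subject_jitter_sd)
            jitter = max(jitter, 0.5)

            lacuna = None
            fractions = None
            if POST in sessions:
                lo, hi = config.n_damaged_range
                n_dam = int(rng.integers(lo, hi + 1))
                rois = rng.choice(lesion_set, size=n_dam, replace=False)
                fr = rng.beta(*config.lesion_beta, size=n_dam)
                fractions = np.zeros(config.n_rois)
                fractions[rois] = fr
                if laterality == "R":
                    fractions = fractions[parc.partner]  # mirror onto the right
                lacuna = _truncated_normal(
                    rng,
                    config.lacuna_volume_mean_cm3,
                    config.lacuna_volume_sd_cm3,
                    config.lacuna_volume_min_cm3,
                )

            record = SubjectRecord(
                subject_id=sid,
                outcome=outcome,
                laterality=laterality,
                sessions=sessions,
                age_years=onset + duration,
                sex=sex,
                onset_age_years=onset,
                duration_years=duration,
                lacuna_volume_cm3=lacuna,
            )
            cohort.subjects.append(record)
            if fractions is not None:
                cohort.lesions[sid] = LesionProfile(sid, fractions, lacuna)

            for session in sessions:
                dmg = fractions if session == POST else None
                sigma = build_population_covariance(config, parc, outcome, session, dmg)
                chol = np.linalg.cholesky(sigma)
                innov = _ar1_innovations(rng, config.n_timepoints, config.n_rois, config.ar_coeff)
                data = jitter * (innov @ chol.T)

                nuis = _smooth_series(rng, config.n_timepoints, 2)
                coupling = rng.normal(0.0, config.nuisance_coupling, size=(2, config.n_rois))
                data = data + nuis @ coupling

                trans_steps = rng.normal(0.0, 0.02, size=(config.n_timepoints, 3))
                rot_steps = rng.normal(0.0, 4e-4, size=(config.n_timepoints, 3))
                motion = np.cumsum(np.hstack([trans_steps, rot_steps]), axis=0)

                cohort.timeseries[(sid, session)] = RoiTimeSeries(
                    sid, session, data, config.tr_seconds
                )
                cohort.motion[(sid, session)] = motion
                cohort.nuisance[(sid, session)] = nuis
    return cohort


def make_lesion_volumes(
    parcellation: Parcellation,
    profile: LesionProfile,
    voxels_per_roi: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Toy 3D label volumes for the volumetric damage path.

    Each region occupies a ``5 x 5`` slab of one axial slice (labels are
    ``roi_id + 1``; 0 is background).  The lacuna mask covers the first
    ``round(fraction * voxels_per_roi)`` voxels of each damaged region, so
    the volume-derived fractions equal the tabular ones up to that
    quantisation.  Purely synthetic geometry: adjacency between regions is
    not meaningful.
    """
    side = int(round(np.sqrt(voxels_per_roi)))
    if side * side != voxels_per_roi:
        raise ValueError("voxels_per_roi must be a perfect square")
    n = parcellation.n_rois
    atlas = np.zeros((n, side, side), dtype=np.int32)
    mask = np.zeros((n, side, side), dtype=np.int32)
    for i in range(n):
        atlas[i] = i + 1
        k = int(round(float(profile.fractions[i]) * voxels_per_roi))
        flat = mask[i].reshape(-1)
        flat[:k] = 1
    return atlas, mask
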
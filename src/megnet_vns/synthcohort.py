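"""Synthetic cohorts: oscillatory time series with controllable phase coupling,
and quantitative twin traits with specified heritability.

Signal model
------------
Each channel is a sum of narrow-band stochastic oscillations, one per 1-Hz
analysis bin.  The instantaneous phase of channel *c* in bin *f* is a mixture
of three independent phase random walks,

    theta_c(t) = sqrt(w) * Psi_m(c)(t) + sqrt(l_c) * Psi_G(t)
                 + sqrt(1 - w - l_c) * Xi_c(t),

where ``Psi_m`` is shared by the channels of module *m*, ``Psi_G`` is shared
globally, ``Xi_c`` is private, ``w`` is the within-module coupling weight and
``l_c`` the channel's global-coupling weight.  Because the three walks share
one diffusion constant and the squared weights sum to one, every channel's
phase has the same marginal diffusion; only the *correlation* between
channels varies, which is exactly what the PLV measures.  This gives direct
analytic control over expected phase locking without simulating oscillator
dynamics.

Group structure
---------------
Patient-like groups are distinguished by their coupling profiles: healthy
controls are strongly modular with weak global coupling; non-responders have
the strongest, channel-heterogeneous global coupling (a synchronised core
that lowers modularity and raises transitivity of the thresholded graph);
responders sit in between.  The per-channel global weights ``l_c`` are drawn
once per subject, so the strongest edges of a globally-coupled subject
concentrate among its high-loading channels.

Twin traits
-----------
Quantitative traits on an MZ/DZ/unrelated pedigree follow the additive
genetic + unique environment (AE) model ``y = X beta + g + e`` with
``cov(g) = 2 * Phi * sigma_g^2`` and ``cov(e) = I * sigma_e^2``, where
``sigma_g^2 = h2`` and ``sigma_e^2 = 1 - h2`` before covariate effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import DEFAULT_BIN_CENTERS, TimeSeriesRun

__all__ = [
    "GROUPS",
    "PATIENT_GROUPS",
    "GroupProfile",
    "DEFAULT_GROUP_PROFILES",
    "CohortSpec",
    "PedigreeSpec",
    "SubjectCouplingProfile",
    "Cohort",
    "TwinData",
    "subject_profile",
    "generate_run",
    "generate_cohort",
    "generate_twin_traits",
    "write_cohort",
    "load_manifest",
    "load_run",
]

#: Canonical group labels: VNS non-responder, VNS responder, healthy control.
GROUPS = ("non-responder", "responder", "control")
PATIENT_GROUPS = ("non-responder", "responder")


@dataclass(frozen=True)
class GroupProfile:
    """Phase-coupling strengths of one group, both in [0, 1]."""

    within_coupling: float
    global_coupling: float

    def __post_init__(self) -> None:
        for v in (self.within_coupling, self.global_coupling):
            if not 0.0 <= v <= 1.0:
                raise ValueError("coupling strengths must lie in [0, 1]")


#: Default profiles, calibrated so that at 10% cost the run-averaged
#: modularity orders controls > responders > non-responders and transitivity
#: orders the reverse (the clinical pattern this package emulates).
DEFAULT_GROUP_PROFILES: dict[str, GroupProfile] = {
    "control": GroupProfile(within_coupling=0.52, global_coupling=0.05),
    "responder": GroupProfile(within_coupling=0.36, global_coupling=0.52),
    "non-responder": GroupProfile(within_coupling=0.22, global_coupling=0.72),
}


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    ``n_per_group`` is (non-responders, responders, controls).  Channels are
    assigned to modules round-robin, so ``n_channels`` need not be divisible
    by ``n_modules`` (module sizes differ by at most one).  Patient runs are
    5 minutes and control runs 6 minutes by default.
    """

    n_per_group: tuple[int, int, int] = (9, 14, 14)
    n_channels: int = 248
    n_runs: int = 3
    run_length_s: float = 300.0
    control_run_length_s: float = 360.0
    fs_hz: float = 508.6
    n_modules: int = 4
    group_profiles: dict[str, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROFILES)
    )
    sedation_fraction: float = 0.5
    # Multiplicative shift of a sedated subject's global coupling; 0 by
    # default (no simulated sedation effect), non-zero for power experiments.
    sedation_effect: float = 0.0
    phase_diffusion: float = 4.0  # rad^2 / s
    core_fraction: float = 0.4
    peripheral_load: float = 0.1
    loading_spread: tuple[float, float] = (0.9, 1.1)
    bin_centers: np.ndarray = field(
        default_factory=lambda: DEFAULT_BIN_CENTERS.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group sizes must be non-negative")
        if self.fs_hz <= 2 * 30.0:
            raise ValueError("sampling rate must exceed twice the highest band edge (30 Hz)")
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules")
        if not 0.0 <= self.sedation_fraction <= 1.0:
            raise ValueError("sedation_fraction must lie in [0, 1]")
        if self.run_length_s <= 0 or self.control_run_length_s <= 0:
            raise ValueError("run length must be positive")
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        for g in GROUPS:
            if g not in self.group_profiles:
                raise ValueError(f"missing group profile for {g!r}")


@dataclass
class SubjectCouplingProfile:
    """Realised coupling parameters of one subject.

    ``module_of[c]`` is the ground-truth community of channel ``c``;
    ``global_load[c]`` is that channel's squared global-coupling weight.
    """

    subject_id: str
    module_of: np.ndarray
    within_coupling: float
    global_load: np.ndarray
    fs_hz: float
    duration_s: float
    phase_diffusion: float = 4.0
    bin_centers: np.ndarray = field(default_factory=lambda: DEFAULT_BIN_CENTERS.copy())

    def __post_init__(self) -> None:
        if np.any(self.global_load < 0) or np.any(
            self.within_coupling + self.global_load > 1.0 + 1e-12
        ):
            raise ValueError("within + global weights must not exceed 1 per channel")


def subject_profile(
    subject_id: str,
    group: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    sedated: bool = False,
) -> SubjectCouplingProfile:
    """Draw one subject's coupling profile from the group-level parameters."""
    prof = spec.group_profiles[group]
    if sedated and spec.sedation_effect != 0.0:
        prof = GroupProfile(
            within_coupling=prof.within_coupling,
            global_coupling=min(prof.global_coupling * (1.0 + spec.sedation_effect), 1.0),
        )
    n = spec.n_channels
    module_of = np.arange(n) % spec.n_modules
    # Bimodal global loadings: a per-subject "core" subset of channels couples
    # to the global phase at (nearly) the full group strength, the periphery
    # only weakly.  Near-equal core loads make the core cohere into the
    # densely synchronised hub that raises transitivity and erodes modularity
    # as global coupling grows.
    lo, hi = spec.loading_spread
    n_core = int(round(spec.core_fraction * n))
    core = np.zeros(n, dtype=bool)
    core[rng.choice(n, size=n_core, replace=False)] = True
    load = np.where(core, 1.0, spec.peripheral_load) * prof.global_coupling
    load = load * rng.uniform(lo, hi, size=n)
    load = np.minimum(load, 1.0 - prof.within_coupling)
    duration = (
        spec.control_run_length_s if group == "control" else spec.run_length_s
    )
    return SubjectCouplingProfile(
        subject_id=subject_id,
        module_of=module_of,
        within_coupling=prof.within_coupling,
        global_load=load,
        fs_hz=spec.fs_hz,
        duration_s=duration,
        phase_diffusion=spec.phase_diffusion,
        bin_centers=spec.bin_centers,
    )


def _phase_walk(rng: np.random.Generator, shape: tuple[int, ...], sigma: float) -> np.ndarray:
    """Random-walk phase: uniform start plus Gaussian increments of std ``sigma``."""
    start = rng.uniform(-np.pi, np.pi, size=shape[:-1] + (1,))
    steps = rng.normal(0.0, sigma, size=shape)
    steps[..., 0] = 0.0
    return start + np.cumsum(steps, axis=-1)


def generate_run(
    profile: SubjectCouplingProfile,
    run_index: int,
    seed: int,
) -> TimeSeriesRun:
    """Generate one run of channels x samples data from a coupling profile.

    Deterministic in ``(profile, run_index, seed)``: the same inputs give
    bit-identical output.
    """
    if profile.duration_s <= 0 or profile.fs_hz <= 0:
        raise ValueError("run length and sampling rate must be positive")
    rng = np.random.default_rng([int(seed), int(run_index)])
    n_ch = profile.module_of.size
    n_samp = int(round(profile.duration_s * profile.fs_hz))
    t = np.arange(n_samp) / profile.fs_hz
    sigma = np.sqrt(profile.phase_diffusion / profile.fs_hz)
    n_modules = int(profile.module_of.max()) + 1

    w = profile.within_coupling
    l = profile.global_load
    a_mod = np.sqrt(w)
    a_glob = np.sqrt(l)[:, None]
    a_ind = np.sqrt(np.clip(1.0 - w - l, 0.0, None))[:, None]

    data = np.zeros((n_ch, n_samp))
    for f in profile.bin_centers:
        psi_mod = _phase_walk(rng, (n_modules, n_samp), sigma)
        psi_glob = _phase_walk(rng, (n_samp,), sigma)
        xi = _phase_walk(rng, (n_ch, n_samp), sigma)
        theta = (
            a_mod * psi_mod[profile.module_of]
            + a_glob * psi_glob[None, :]
            + a_ind * xi
        )
        data += np.cos(2.0 * np.pi * f * t[None, :] + theta)
    return TimeSeriesRun(data=data, fs_hz=profile.fs_hz)


@dataclass
class Cohort:
    """In-memory synthetic cohort: manifest plus per-subject runs and profiles."""

    manifest: pd.DataFrame
    runs: dict[str, list[TimeSeriesRun]]
    profiles: dict[str, SubjectCouplingProfile]
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort: manifest rows plus ``n_runs`` runs per subject."""
    ss = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(ss)

    rows = []
    runs: dict[str, list[TimeSeriesRun]] = {}
    profiles: dict[str, SubjectCouplingProfile] = {}
    prefixes = {"non-responder": "NR", "responder": "R", "control": "C"}

    for group, n in zip(GROUPS, spec.n_per_group):
        if n == 0:
            continue
        n_sedated = int(round(spec.sedation_fraction * n)) if group != "control" else 0
        sed_flags = np.zeros(n, dtype=int)
        sed_flags[master.choice(n, size=n_sedated, replace=False)] = 1
        if group == "control":
            ages = np.clip(master.normal(28.6, 3.9, size=n), 22.0, 40.0)
        else:
            ages = np.clip(master.normal(11.3, 6.9, size=n), 1.0, 21.0)
        sexes = master.choice(["M", "F"], size=n)
        for i in range(n):
            sid = f"{prefixes[group]}{i + 1:02d}"
            sub_seed = int(master.integers(0, 2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            prof = subject_profile(sid, group, spec, sub_rng, sedated=bool(sed_flags[i]))
            profiles[sid] = prof
            runs[sid] = [
                generate_run(prof, run_index=r, seed=sub_seed)
                for r in range(spec.n_runs)
            ]
            rows.append(
                dict(
                    subject_id=sid,
                    group=group,
                    sedation=int(sed_flags[i]),
                    age=float(np.round(ages[i], 1)),
                    sex=str(sexes[i]),
                    seed=sub_seed,
                )
            )
    manifest = pd.DataFrame(rows)
    return Cohort(manifest=manifest, runs=runs, profiles=profiles, spec=spec)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write runs (HDF5 + JSON sidecar) and a manifest TSV; returns manifest path."""
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_paths_col = []
    for row in cohort.manifest.itertuples():
        paths = []
        for r, run in enumerate(cohort.runs[row.subject_id]):
            p = out / f"{row.subject_id}_run{r}.h5"
            with h5py.File(p, "w") as f:
                f.create_dataset("data", data=run.data.astype(np.float32))
            sidecar = dict(
                fs_hz=run.fs_hz, channel_names=run.channel_names, seed=int(row.seed)
            )
            p.with_suffix(".json").write_text(json.dumps(sidecar))
            paths.append(str(p))
        run_paths_col.append(";".join(paths))
    manifest = cohort.manifest.copy()
    manifest["run_paths"] = run_paths_col
    mpath = out / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    return mpath


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_run(path: str | Path) -> TimeSeriesRun:
    """Load one run written by :func:`write_cohort`."""
    import h5py

    p = Path(path)
    with h5py.File(p, "r") as f:
        data = f["data"][()]
    sidecar = json.loads(p.with_suffix(".json").read_text())
    return TimeSeriesRun(
        data=np.asarray(data, dtype=float),
        fs_hz=float(sidecar["fs_hz"]),
        channel_names=list(sidecar["channel_names"]),
    )


# ---------------------------------------------------------------------------
# Twin traits
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSpec:
    """Design of a synthetic twin pedigree and its simulated trait."""

    n_mz_pairs: int = 19
    n_dz_pairs: int = 13
    n_unrelated: int = 27
    h2_true: float = 0.6
    covariate_betas: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_unrelated) < 0:
            raise ValueError("pedigree counts must be non-negative")


@dataclass
class TwinData:
    """Pedigree table, trait vector and covariates of one simulated replicate."""

    pedigree: pd.DataFrame
    traits: pd.Series
    covariates: pd.DataFrame
    genetic_component: pd.Series


def _pedigree_table(spec: PedigreeSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    fam = 0
    for _ in range(spec.n_mz_pairs):
        fam += 1
        sex = int(rng.integers(1, 3))  # MZ co-twins share sex
        for k in (1, 2):
            rows.append((f"F{fam:03d}", f"F{fam:03d}-{k}", "0", "0", sex, "MZ"))
    for _ in range(spec.n_dz_pairs):
        fam += 1
        for k in (1, 2):
            rows.append(
                (f"F{fam:03d}", f"F{fam:03d}-{k}", "0", "0", int(rng.integers(1, 3)), "DZ")
            )
    for _ in range(spec.n_unrelated):
        fam += 1
        rows.append(
            (f"F{fam:03d}", f"F{fam:03d}-1", "0", "0", int(rng.integers(1, 3)), "NT")
        )
    return pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "zygosity"],
    )


def generate_twin_traits(spec: PedigreeSpec) -> TwinData:
    """Simulate an AE trait on an MZ/DZ/unrelated pedigree.

    ``y = X beta + g + e`` with ``cov(g) = h2 * 2Phi`` (via an eigen
    factorisation of the kinship matrix) and ``cov(e) = (1 - h2) * I``.
    Covariate effects (keys among age, age2, sex, age_sex, age2_sex) are added
    on top of the unit-variance genetic + environmental part.
    """
    from .heritability import build_kinship  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    ped = _pedigree_table(spec, rng)
    n = len(ped)
    if n == 0:
        raise ValueError("empty pedigree")

    # Family-shared age; twins are exactly the same age.
    fam_age = {f: float(np.clip(rng.normal(28.6, 3.9), 22.0, 36.0)) for f in ped.family_id.unique()}
    age = ped.family_id.map(fam_age).to_numpy()
    sex = (ped.sex.to_numpy() == 2).astype(float)  # 0/1 indicator

    kin = build_kinship(ped)
    lam, vec = np.linalg.eigh(kin.values)
    lam = np.clip(lam, 0.0, None)
    g = vec @ (np.sqrt(lam) * rng.normal(size=n)) * np.sqrt(spec.h2_true)
    e = rng.normal(size=n) * np.sqrt(1.0 - spec.h2_true)

    age_c = age - age.mean()
    terms = {
        "age": age_c,
        "age2": age_c**2,
        "sex": sex,
        "age_sex": age_c * sex,
        "age2_sex": age_c**2 * sex,
    }
    fixed = np.zeros(n)
    for name, beta in spec.covariate_betas.items():
        if name not in terms:
            raise ValueError(f"unknown covariate term {name!r}")
        fixed += beta * terms[name]

    y = fixed + g + e
    ids = ped.individual_id
    return TwinData(
        pedigree=ped,
        traits=pd.Series(y, index=ids, name="trait"),
        covariates=pd.DataFrame({"age": age, "sex": sex}, index=ids),
        genetic_component=pd.Series(g, index=ids, name="g"),
    )
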
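"""Synthetic single-dose pharmacometabolomics study generator.

Emulates the data the pipeline consumes, with exported ground truth so every
downstream stage can be tested for recovery:

* one-compartment oral-absorption concentration–time profiles for a cohort
  (default 37 subjects, 500 mg dose) calibrated to the reported single-dose
  regime — population Kel 0.09 h⁻¹, Cmax ≈ 35.5 µg/mL — with lognormal
  between-subject variability and multiplicative assay noise;
* a features × injections LC-MS intensity matrix with paired pre/post
  samples per subject, pooled-QC injections every ``qc_interval`` samples,
  randomized injection order, multiplicative smooth injection-order drift
  shared by QC and study samples, planted pre/post differential features and
  planted (linear or rank-monotone) metabolite↔parameter associations;
* a subject trait table around clinically plausible centers;
* a GMT pathway database with exactly one pathway enriched for the planted
  differential features.

All randomness flows through one seed; each stage draws from its own
sub-stream so partial re-runs are stable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import Pathway, PathwayDB
from .pknca import ConcentrationProfile, PKParameters
from .preprocess import FeatureMatrix

__all__ = [
    "PopulationPK",
    "SimulationConfig",
    "GroundTruth",
    "simulate_pk_profiles",
    "simulate_traits",
    "simulate_feature_matrix",
    "simulate_pathways",
    "simulate_study",
    "SimulatedStudy",
]

# (center, SD) of the trait panel; sex is Bernoulli(0.5), hematocrit is
# generated jointly with hemoglobin (r = 0.9) — the only deliberate
# trait–trait correlation.
TRAIT_CENTERS: dict[str, tuple[float, float]] = {
    "age": (28.0, 6.8),
    "bmi": (24.2, 2.7),
    "systolic_bp": (118.0, 10.0),
    "total_cholesterol": (180.0, 30.0),
    "creatinine": (0.9, 0.15),
    "ast": (24.0, 7.0),
    "alt": (22.0, 9.0),
    "total_bilirubin": (0.7, 0.25),
    "hemoglobin": (14.5, 1.3),
    "hematocrit": (43.0, 3.5),
    "leukocytes": (6.5, 1.5),
    "fasting_glucose": (88.0, 7.0),
}

PK_PARAMETERS = ("auc0t", "cmax", "tmax", "kel", "t_half")


@dataclass(frozen=True)
class PopulationPK:
    """Population means and lognormal CVs of the one-compartment parameters.

    Defaults reproduce the reported single-dose regime: with ka = 1.3 h⁻¹,
    ke = 0.09 h⁻¹, V = 11.5 L and F = 1 at 500 mg, the analytic Tmax is
    ≈ 2.2 h and Cmax ≈ 35.6 µg/mL; Kel's CV of 0.22 matches a 0.02 SD
    around 0.09 h⁻¹.
    """

    ka: float = 1.3  # absorption rate, 1/h
    ke: float = 0.09  # elimination rate, 1/h
    v: float = 11.5  # apparent volume of distribution, L
    f: float = 1.0  # bioavailable fraction
    cv_ka: float = 0.30
    cv_ke: float = 0.22
    cv_v: float = 0.20
    cv_f: float = 0.0

    def __post_init__(self) -> None:
        if min(self.ka, self.ke, self.v) <= 0 or not (0 < self.f <= 1):
            raise ValueError("PK population parameters must be positive (0<F≤1)")
        if min(self.cv_ka, self.cv_ke, self.cv_v, self.cv_f) < 0:
            raise ValueError("CVs must be non-negative")


DEFAULT_TIMES = (
    0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5,
    4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0, 36.0, 48.0,
)


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world of the synthetic study."""

    n_subjects: int = 37
    dose_mg: float = 500.0
    sampling_times: tuple[float, ...] = DEFAULT_TIMES
    pk_population: PopulationPK = field(default_factory=PopulationPK)
    n_features: int = 2000
    n_differential: int = 70
    effect_sizes: tuple[float, float] = (0.5, 1.5)  # |log-fold-change|, natural log
    n_planted_edges: int = 10
    edge_strength: float = 0.5
    edge_forms: tuple[str, ...] = ("linear", "monotone")
    drift_magnitude: float = 0.3
    qc_interval: int = 10
    noise_cv: float = 0.10
    n_pathways: int = 20
    planted_pathway_size: int = 12
    planted_pathway_hits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.n_differential > self.n_features:
            raise ValueError("n_differential exceeds n_features")
        if self.n_planted_edges > self.n_features:
            raise ValueError("more planted edges than features")
        if self.qc_interval < 2:
            raise ValueError("qc_interval must be at least 2")
        if self.noise_cv < 0 or self.drift_magnitude < 0:
            raise ValueError("noise_cv and drift_magnitude must be non-negative")
        t = np.asarray(self.sampling_times, float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must start at 0 and increase strictly")
        if t[-1] < 3 * np.log(2) / self.pk_population.ke:
            raise ValueError("sampling must cover at least 3 population half-lives")

    def rng(self, stage: int) -> np.random.Generator:
        """Seeded sub-stream for one simulation stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    differential_feature_ids: list[str]
    true_log_fold_change: dict[str, float]
    planted_edges: list[dict]  # {metabolite_id, parameter_name, sign, form}
    enriched_pathway_id: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# pharmacokinetics
# ---------------------------------------------------------------------------


def one_compartment_conc(
    t: np.ndarray, dose: float, ka: float, ke: float, v: float, f: float
) -> np.ndarray:
    """C(t) = F·D·ka / (V·(ka−ke)) · (e^{−ke·t} − e^{−ka·t})."""
    t = np.asarray(t, float)
    return f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def analytic_pk(
    dose: float, ka: float, ke: float, v: float, f: float, t_last: float
) -> dict:
    """Closed-form Tmax/Cmax/Kel/T1/2 and AUC over [0, t_last]."""
    tmax = np.log(ka / ke) / (ka - ke)
    cmax = float(one_compartment_conc(np.array([tmax]), dose, ka, ke, v, f)[0])
    pref = f * dose * ka / (v * (ka - ke))
    auc = pref * (
        (1 - np.exp(-ke * t_last)) / ke - (1 - np.exp(-ka * t_last)) / ka
    )
    return {
        "tmax": float(tmax),
        "cmax": cmax,
        "kel": ke,
        "t_half": float(np.log(2) / ke),
        "auc0t": float(auc),
    }


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    if cv == 0:
        return np.full(size, mean)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(np.log(mean) - sigma * sigma / 2, sigma, size))


def subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def simulate_pk_profiles(
    cfg: SimulationConfig,
) -> tuple[list[ConcentrationProfile], list[PKParameters]]:
    """Noisy cohort profiles plus the noise-free true PK parameters.

    Subject (ka, ke, V, F) are lognormal around the population means; draws
    with ka ≈ ke (the model's removable singularity) are rejected and
    resampled.
    """
    rng = cfg.rng(stage=0)
    pop = cfg.pk_population
    n = cfg.n_subjects
    t = np.asarray(cfg.sampling_times, float)
    sids = subject_ids(n)
    profiles, params = [], []
    sigma = np.sqrt(np.log1p(cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0
    for sid in sids:
        for _ in range(100):
            ka = float(_lognormal(rng, pop.ka, pop.cv_ka, 1)[0])
            ke = float(_lognormal(rng, pop.ke, pop.cv_ke, 1)[0])
            if abs(ka - ke) > 1e-3:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw ka != ke")
        v = float(_lognormal(rng, pop.v, pop.cv_v, 1)[0])
        f = pop.f if pop.cv_f == 0 else float(
            np.clip(_lognormal(rng, pop.f, pop.cv_f, 1)[0], 1e-6, 1.0)
        )
        conc = one_compartment_conc(t, cfg.dose_mg, ka, ke, v, f)
        if sigma > 0:
            conc = conc * np.exp(rng.normal(0.0, sigma, conc.size))
        conc[t == 0] = 0.0
        profiles.append(
            ConcentrationProfile(subject_id=sid, times=t, concentrations=conc)
        )
        true = analytic_pk(cfg.dose_mg, ka, ke, v, f, float(t[-1]))
        params.append(
            PKParameters(
                subject_id=sid,
                auc0t=true["auc0t"],
                cmax=true["cmax"],
                tmax=true["tmax"],
                kel=true["kel"],
                t_half=true["t_half"],
                n_terminal_points=0,
                terminal_r2=np.nan,
            )
        )
    return profiles, params


def true_pk_table(params: list[PKParameters]) -> pd.DataFrame:
    """Generating (noise-free) parameters as a subjects-indexed table."""
    return pd.DataFrame(
        {p: [getattr(r, p) for r in params] for p in PK_PARAMETERS},
        index=[r.subject_id for r in params],
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_traits(cfg: SimulationConfig) -> pd.DataFrame:
    """Subject trait table: sex plus the clinical/laboratory panel."""
    rng = cfg.rng(stage=1)
    n = cfg.n_subjects
    data = {"sex": rng.integers(0, 2, n).astype(float)}
    hb_c, hb_s = TRAIT_CENTERS["hemoglobin"]
    hct_c, hct_s = TRAIT_CENTERS["hematocrit"]
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    rho = 0.9
    for name, (center, sd) in TRAIT_CENTERS.items():
        if name == "hemoglobin":
            data[name] = hb_c + hb_s * z1
        elif name == "hematocrit":
            data[name] = hct_c + hct_s * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        else:
            data[name] = center + sd * rng.normal(size=n)
    return pd.DataFrame(data, index=subject_ids(n))


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


def _injection_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Randomized run order with a QC before every block of qc_interval samples
    and one after the last sample."""
    n = cfg.n_subjects
    sids = subject_ids(n)
    samples = [(s, tp) for s in sids for tp in ("pre", "post")]
    order = rng.permutation(len(samples))
    samples = [samples[i] for i in order]
    rows = []
    inj, qc_idx, sample_idx = 1, 1, 1
    for i, (sid, tp) in enumerate(samples):
        if i % cfg.qc_interval == 0:
            rows.append((f"QC{qc_idx:02d}", "", "QC", inj, ""))
            qc_idx += 1
            inj += 1
        period = 1 if sids.index(sid) < n // 2 else 2
        rows.append((f"INJ{sample_idx:03d}", sid, tp, inj, period))
        sample_idx += 1
        inj += 1
    rows.append((f"QC{qc_idx:02d}", "", "QC", inj, ""))
    meta = pd.DataFrame(
        rows,
        columns=["injection_id", "subject_id", "timepoint", "injection_order", "period"],
    ).set_index("injection_id")
    return meta


def simulate_feature_matrix(
    cfg: SimulationConfig,
    pk_params: list[PKParameters],
    traits: pd.DataFrame,
) -> tuple[FeatureMatrix, GroundTruth]:
    """LC-MS intensity matrix with planted structure and its ground truth.

    Intensity model (multiplicative): lognormal per-feature baseline ×
    pre/post effect (differential features) × association term (planted
    edges, applied to post-dose samples) × smooth injection-order drift ×
    lognormal noise. QC injections start from the per-feature mean of all
    study samples before drift/noise, so correction quality is measurable
    against an exact target.
    """
    sids = subject_ids(cfg.n_subjects)
    if list(traits.index) != sids or [p.subject_id for p in pk_params] != sids:
        raise ValueError("pk and traits must cover the identical subject ids")
    rng = cfg.rng(stage=2)
    n_feat = cfg.n_features
    fids = [f"F{i + 1:04d}" for i in range(n_feat)]

    # planted differential features and their log-fold-changes
    diff_idx = rng.choice(n_feat, size=cfg.n_differential, replace=False)
    diff_idx.sort()
    lo, hi = cfg.effect_sizes
    lfc = rng.uniform(lo, hi, cfg.n_differential) * rng.choice(
        [-1.0, 1.0], cfg.n_differential
    )
    lfc_map = {fids[i]: float(v) for i, v in zip(diff_idx, lfc)}

    # planted edges live on differential features so they survive selection
    # into the network stage
    # tmax is excluded from plantable targets: its measured counterpart is the
    # sampling-grid argmax, a coarse discretization no method could recover a
    # planted continuous association from (it still enters the network as a
    # tested node).
    pk_tab = true_pk_table(pk_params)
    targets = [c for c in pk_tab.columns if c != "tmax"] + [
        c for c in traits.columns if c != "sex"
    ]
    edge_feat_idx = rng.choice(diff_idx, size=cfg.n_planted_edges, replace=False)
    edges = []
    for j, fi in enumerate(sorted(edge_feat_idx)):
        pname = targets[int(rng.integers(0, len(targets)))]
        form = cfg.edge_forms[j % len(cfg.edge_forms)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        edges.append(
            {
                "metabolite_id": fids[fi],
                "parameter_name": pname,
                "sign": "+" if sign > 0 else "-",
                "form": form,
            }
        )

    # standardized parameter values per subject, for the association terms
    param_values = pd.concat([pk_tab, traits.drop(columns=["sex"])], axis=1)
    zscores = (param_values - param_values.mean()) / param_values.std(ddof=0)

    meta = _injection_layout(cfg, cfg.rng(stage=3))
    baseline = 10.0 ** rng.uniform(4.0, 7.0, n_feat)

    # noise-free study intensities, features × study injections
    study_ids = [i for i in meta.index if meta.loc[i, "timepoint"] != "QC"]
    X = np.tile(baseline[:, None], (1, len(study_ids)))
    col_of = {inj: k for k, inj in enumerate(study_ids)}
    subj_of = meta.loc[study_ids, "subject_id"]
    tp_of = meta.loc[study_ids, "timepoint"]
    for i, fid in zip(diff_idx, [fids[i] for i in diff_idx]):
        post_cols = [col_of[inj] for inj in study_ids if tp_of[inj] == "post"]
        X[i, post_cols] *= np.exp(lfc_map[fid])
    for edge in edges:
        i = fids.index(edge["metabolite_id"])
        z = zscores[edge["parameter_name"]]
        s = 1.0 if edge["sign"] == "+" else -1.0
        # linear terms are exactly affine in the parameter, kept positive by
        # anchoring at the cohort minimum, and rescaled to cohort mean one so
        # they neither shift the pre/post contrast nor break r = ±1
        if edge["form"] == "linear":
            raw = 1.0 + cfg.edge_strength * (s * z - float((s * z).min()))
            mult = raw / raw.mean()
        else:  # rank-monotone: intensity ∝ exp(parameter z-score)
            mult = np.exp(s * cfg.edge_strength * z)
        for inj in study_ids:
            if tp_of[inj] == "post":
                X[i, col_of[inj]] *= float(mult.loc[subj_of[inj]])

    # QC truth: per-feature mean over study samples, before drift/noise
    qc_ids = [i for i in meta.index if meta.loc[i, "timepoint"] == "QC"]
    qc_truth = X.mean(axis=1)

    # assemble full matrix in metadata order, then drift and noise
    full = np.empty((n_feat, len(meta.index)))
    for k, inj in enumerate(meta.index):
        full[:, k] = qc_truth if inj in qc_ids else X[:, col_of[inj]]

    order = meta["injection_order"].to_numpy(float)
    u = (order - order.min()) / (order.max() - order.min())
    if cfg.drift_magnitude > 0:
        trend_amp = rng.uniform(0.5, 1.0, n_feat) * rng.choice([-1.0, 1.0], n_feat)
        wave_amp = rng.uniform(0.0, 0.5, n_feat)
        phase = rng.uniform(0, 2 * np.pi, n_feat)
        g = cfg.drift_magnitude * (
            trend_amp[:, None] * (u[None, :] - 0.5)
            + wave_amp[:, None] * np.sin(np.pi * u[None, :] + phase[:, None])
        )
        full *= np.exp(g)
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
        full *= np.exp(rng.normal(0.0, sigma, full.shape))

    intensities = pd.DataFrame(full, index=fids, columns=list(meta.index))
    fm = FeatureMatrix(intensities=intensities, metadata=meta)
    gt = GroundTruth(
        differential_feature_ids=[fids[i] for i in diff_idx],
        true_log_fold_change=lfc_map,
        planted_edges=edges,
    )
    return fm, gt


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

PATHWAY_SOURCES = ("KEGG", "Reactome", "WikiPathways")


def simulate_pathways(
    cfg: SimulationConfig,
    feature_ids: list[str],
    ground_truth: GroundTruth,
) -> PathwayDB:
    """GMT-style pathway database with one planted enriched pathway.

    The planted pathway holds ``planted_pathway_hits`` differential features
    among ``planted_pathway_size`` members; the remaining pathways draw
    members uniformly with sizes in [5, 150]. Sets ``enriched_pathway_id``
    on the ground truth.
    """
    rng = cfg.rng(stage=4)
    diff = ground_truth.differential_feature_ids
    # null worlds (few/no differential features) still emit the first
    # pathway, just without a planted enrichment claim
    n_hits = min(cfg.planted_pathway_hits, len(diff))
    non_diff = [f for f in feature_ids if f not in set(diff)]
    planted_members = list(rng.choice(diff, size=n_hits, replace=False)) + list(
        rng.choice(
            non_diff, size=cfg.planted_pathway_size - n_hits, replace=False
        )
    )
    pathways = [
        Pathway(
            pathway_id="PW000",
            source="Reactome",
            members=frozenset(planted_members),
        )
    ]
    max_size = min(150, len(feature_ids))
    for i in range(1, cfg.n_pathways):
        size = int(rng.integers(5, max_size + 1))
        members = rng.choice(feature_ids, size=size, replace=False)
        pathways.append(
            Pathway(
                pathway_id=f"PW{i:03d}",
                source=PATHWAY_SOURCES[i % len(PATHWAY_SOURCES)],
                members=frozenset(members),
            )
        )
    ground_truth.enriched_pathway_id = "PW000" if n_hits > 0 else None
    return PathwayDB(pathways)


# ---------------------------------------------------------------------------
# whole-study convenience bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    profiles: list[ConcentrationProfile]
    true_pk: list[PKParameters]
    traits: pd.DataFrame
    feature_matrix: FeatureMatrix
    pathways: PathwayDB
    ground_truth: GroundTruth


def simulate_study(cfg: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate every input of one synthetic study under one seed."""
    cfg = SimulationConfig() if cfg is None else cfg
    profiles, true_pk = simulate_pk_profiles(cfg)
    traits = simulate_traits(cfg)
    fm, gt = simulate_feature_matrix(cfg, true_pk, traits)
    db = simulate_pathways(cfg, fm.feature_ids, gt)
    return SimulatedStudy(
        config=cfg,
        profiles=profiles,
        true_pk=true_pk,
        traits=traits,
        feature_matrix=fm,
        pathways=db,
        ground_truth=gt,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write every input in the pipeline's CSV/GMT/JSON dialect."""
    import pathlib

    from .enrich import write_gmt

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    conc = pd.DataFrame(
        [
            (p.subject_id, t, c)
            for p in study.profiles
            for t, c in zip(p.times, p.concentrations)
        ],
        columns=["subject", "time_h", "conc_ug_per_ml"],
    )
    conc.to_csv(out / "concentrations.csv", index=False, float_format="%.10g")
    study.feature_matrix.to_csv(out / "features.csv", out / "injections.csv")
    study.traits.to_csv(out / "traits.csv", index_label="subject", float_format="%.10g")
    write_gmt(study.pathways, out / "pathways.gmt")
    study.ground_truth.to_json(out / "ground_truth.json")
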
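"""Synthetic two-reporter dyad generator with known latent truth.

Per construct and dyad the generator draws (eta_self, delta) from a bivariate
normal whose means are shifted by binary covariate effects, sets
eta_parent = eta_self + delta, produces continuous item responses
y* = nu + lambda * eta + eps, and thresholds them into 3-point ordinal
ratings.  Measurement non-invariance is a separate, explicit channel:
(item position, 'loading'|'intercept', offset) applied to the parent side.

Items are generated ordinally but analysed as continuous downstream; that
deliberate mismatch is the realistic test condition for the ML pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import instruments
from .instruments import (
    CONSTRUCTS,
    item_columns,
    k6_columns,
    subscale_definition,
    reference_item_moments,
    SDQ_MAX,
)


class ConfigError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass
class CovariateEffect:
    """Binary covariate: prevalence of the coded-1 level and its latent effects."""

    prevalence: float
    beta_self: float = 0.0
    beta_delta: float = 0.0

    def validate(self, name: str) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(f"covariate {name}: prevalence outside [0,1]")


@dataclass
class ConstructConfig:
    """Generative quantities for one construct (both reporters)."""

    name: str
    loadings_self: list[float]
    loadings_parent: list[float]
    intercepts_self: list[float]
    intercepts_parent: list[float]
    resid_sd_self: list[float]
    resid_sd_parent: list[float]
    mean_self: float = 0.0
    sd_self: float = 1.0
    mean_delta: float = 0.0
    sd_delta: float = 0.5
    cov_self_delta: float = 0.0
    # thresholds: per item two cut points mapping y* to {0,1,2}
    thresholds_self: list[tuple[float, float]] = field(default_factory=list)
    thresholds_parent: list[tuple[float, float]] = field(default_factory=list)
    # (item position 0-4, 'loading'|'intercept', offset) applied to parent
    noninvariance: list[tuple[int, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        for attr in ("loadings_self", "loadings_parent", "intercepts_self",
                     "intercepts_parent", "resid_sd_self", "resid_sd_parent"):
            if len(getattr(self, attr)) != 5:
                raise ConfigError(f"{self.name}.{attr}: need 5 entries")
        if self.sd_self <= 0 or self.sd_delta <= 0:
            raise ConfigError(f"{self.name}: latent SDs must be positive")
        if abs(self.cov_self_delta) > self.sd_self * self.sd_delta:
            raise ConfigError(f"{self.name}: |cov_self_delta| exceeds sd_self*sd_delta")
        for ths in (self.thresholds_self, self.thresholds_parent):
            if len(ths) != 5:
                raise ConfigError(f"{self.name}: need 5 threshold pairs per reporter")
            for t1, t2 in ths:
                if not t1 < t2:
                    raise ConfigError(f"{self.name}: thresholds must be increasing")
        for pos, kind, _ in self.noninvariance:
            if pos not in range(5) or kind not in ("loading", "intercept"):
                raise ConfigError(f"{self.name}: bad noninvariance entry")

    def effective_parent_measurement(self) -> tuple[np.ndarray, np.ndarray]:
        lam = np.array(self.loadings_parent, dtype=float)
        nu = np.array(self.intercepts_parent, dtype=float)
        for pos, kind, off in self.noninvariance:
            if kind == "loading":
                lam[pos] += off
            else:
                nu[pos] += off
        return lam, nu


@dataclass
class MissingnessConfig:
    """Unit nonresponse (logistic on covariates) plus item-level MCAR."""

    logit_intercept: float = 20.0  # effectively no missingness by default
    logit_coefs: dict[str, float] = field(default_factory=dict)
    item_mcar_rate: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.item_mcar_rate <= 1.0:
            raise ConfigError("item_mcar_rate outside [0,1]")


@dataclass
class GeneratorConfig:
    n_dyads: int
    seed: int
    constructs: dict[str, ConstructConfig]
    covariates: dict[str, CovariateEffect] = field(default_factory=dict)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    survey_weight_sd: float = 0.3  # lognormal spread of emitted weights
    # emit the continuous responses y* instead of thresholding them; the
    # linear-ML analysis is then correctly specified (parameter-recovery and
    # coverage studies), whereas ordinal emission is the realistic condition
    continuous_items: bool = False

    def validate(self) -> None:
        if self.n_dyads < 1:
            raise ConfigError("n_dyads must be positive")
        for cc in self.constructs.values():
            cc.validate()
        for name, cov in self.covariates.items():
            cov.validate(name)
        unknown = set(self.missingness.logit_coefs) - set(self.covariates)
        if unknown:
            raise ConfigError(f"missingness coefficients on unknown covariates: {unknown}")
        self.missingness.validate()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Per-dyad latent draws plus the exact config and realized masks."""

    config: GeneratorConfig
    eta_self: dict[str, np.ndarray]
    delta: dict[str, np.ndarray]
    eta_parent: dict[str, np.ndarray]
    covariate_values: dict[str, np.ndarray]
    complete_flag: np.ndarray | None = None
    item_mask: pd.DataFrame | None = None  # True where blanked

    def save(self, path) -> None:
        payload = {
            "config": json.loads(self.config.to_json()),
            "eta_self": {k: v.tolist() for k, v in self.eta_self.items()},
            "delta": {k: v.tolist() for k, v in self.delta.items()},
            "eta_parent": {k: v.tolist() for k, v in self.eta_parent.items()},
            "covariates": {k: v.tolist() for k, v in self.covariate_values.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

#: standardized latent discrepancy mean per construct for the default config
DEFAULT_DELTA_STD = {
    "conduct": -0.9, "emotion": -0.4, "peer": -0.2, "prosocial": 0.5,
    "hyperactivity": -0.55,
}
DEFAULT_COV_STD = {
    "conduct": -0.49, "emotion": -0.58, "peer": -0.35, "prosocial": -0.48,
    "hyperactivity": -0.4,
}


def default_construct_config(
    name: str,
    delta_std_mean: float | None = None,
    noninvariance: list[tuple[int, str, float]] | None = None,
) -> ConstructConfig:
    """A plausible invariant measurement model, calibrated so the ordinal
    item marginals land near the published reference moments."""
    loadings = [1.0, 0.9, 1.1, 0.8, 1.0]
    intercepts = [0.0, 0.05, -0.05, 0.1, 0.0]
    resid = [0.6, 0.7, 0.6, 0.7, 0.65]
    sd_delta = 0.35
    dstd = DEFAULT_DELTA_STD[name] if delta_std_mean is None else delta_std_mean
    cc = ConstructConfig(
        name=name,
        loadings_self=list(loadings), loadings_parent=list(loadings),
        intercepts_self=list(intercepts), intercepts_parent=list(intercepts),
        resid_sd_self=list(resid), resid_sd_parent=list(resid),
        mean_self=0.0, sd_self=0.55,
        mean_delta=dstd * sd_delta, sd_delta=sd_delta,
        cov_self_delta=DEFAULT_COV_STD[name] * 0.55 * sd_delta,
        thresholds_self=[(-0.3, 0.9)] * 5,
        thresholds_parent=[(-0.3, 0.9)] * 5,
        noninvariance=list(noninvariance or []),
    )
    # pull thresholds toward the published item marginals
    for reporter in ("self", "parent"):
        mean, sd = reference_item_moments(name, reporter)
        _set_thresholds_for_targets(cc, reporter, mean, sd)
    return cc


def default_config(
    n_dyads: int = 2000,
    seed: int = 20230511,
    constructs=("conduct", "emotion", "peer", "prosocial"),
    with_covariates: bool = True,
    with_missingness: bool = False,
) -> GeneratorConfig:
    cov = {}
    if with_covariates:
        cov = {
            "sex": CovariateEffect(0.507, beta_self=-0.2, beta_delta=0.06),
            "distress": CovariateEffect(0.346, beta_self=0.16, beta_delta=0.06),
            "edu": CovariateEffect(0.563, beta_self=-0.07, beta_delta=-0.04),
        }
    miss = MissingnessConfig()
    if with_missingness:
        miss = MissingnessConfig(
            logit_intercept=1.2,
            logit_coefs={"edu": 0.5, "distress": -0.4},
            item_mcar_rate=0.02,
        )
    cfg = GeneratorConfig(
        n_dyads=n_dyads, seed=seed,
        constructs={c: default_construct_config(c) for c in constructs},
        covariates=cov, missingness=miss,
    )
    # recalibrate thresholds under the covariate-shifted latent marginals
    for c, cc in cfg.constructs.items():
        for reporter in ("self", "parent"):
            mean, sd = reference_item_moments(c, reporter)
            _set_thresholds_for_targets(cc, reporter, mean, sd, config=cfg)
    cfg.validate()
    return cfg


def invariance_scenario_config(
    construct: str = "conduct",
    n_dyads: int = 3000,
    seed: int = 0,
    delta_std: float = -0.3,
    noninvariance: list[tuple[int, str, float]] | None = None,
) -> GeneratorConfig:
    """A config whose *ordinal* measurement is invariant across reporters:
    identical loadings, intercepts, residual SDs and thresholds, so any
    reporter difference flows through the latent discrepancy only.  The
    explicit ``noninvariance`` channel is then the sole violation source.

    Note the default config is deliberately *not* invariant in this sense:
    its reporter-specific threshold calibration mimics real instruments.
    """
    cc = default_construct_config(construct, delta_std_mean=delta_std,
                                  noninvariance=noninvariance)
    # common thresholds, chosen at the midpoint of the two reporters' latent
    # locations so neither side sits in an extreme tail of the cut points
    common = [(-0.35 + 0.5 * cc.mean_delta, 0.75 + 0.5 * cc.mean_delta)] * 5
    cc.thresholds_self = list(common)
    cc.thresholds_parent = list(common)
    cfg = GeneratorConfig(n_dyads=n_dyads, seed=seed, constructs={construct: cc})
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _covariate_patterns(config: GeneratorConfig):
    """All binary covariate combinations with probabilities (independence)."""
    names = list(config.covariates)
    pats = [([], 1.0)]
    for name in names:
        prev = config.covariates[name].prevalence
        pats = [
            (vals + [v], p * (prev if v else 1 - prev))
            for vals, p in pats
            for v in (0, 1)
        ]
    return names, pats


def _latent_moments(cc: ConstructConfig, config: GeneratorConfig, reporter: str):
    """Marginal mean/var of the latent score for one reporter, integrating
    over the covariate distribution."""
    names = list(config.covariates)
    b_self = np.array([config.covariates[n].beta_self for n in names])
    b_delta = np.array([config.covariates[n].beta_delta for n in names])
    prev = np.array([config.covariates[n].prevalence for n in names])
    if reporter == "self":
        base_mean, base_var, b = cc.mean_self, cc.sd_self**2, b_self
    else:
        base_mean = cc.mean_self + cc.mean_delta
        base_var = cc.sd_self**2 + cc.sd_delta**2 + 2 * cc.cov_self_delta
        b = b_self + b_delta
    mean = base_mean + float(b @ prev) if names else base_mean
    var = base_var + float((b**2) @ (prev * (1 - prev))) if names else base_var
    return mean, var


def generate_dyads(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a dyad data frame (CSV dialect, raw ratings) and its latent truth.

    Deterministic given ``config.seed``.  Reverse-flagged items are emitted on
    the raw metric (flipped back), so the frame round-trips through the same
    scoring path as real data.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_dyads
    names = list(config.covariates)
    x = {
        name: (rng.random(n) < config.covariates[name].prevalence).astype(int)
        for name in names
    }

    frame = pd.DataFrame({"dyad_id": np.arange(n)})
    eta_self_all: dict[str, np.ndarray] = {}
    delta_all: dict[str, np.ndarray] = {}
    eta_parent_all: dict[str, np.ndarray] = {}

    for cname, cc in config.constructs.items():
        mean_s = np.full(n, cc.mean_self, dtype=float)
        mean_d = np.full(n, cc.mean_delta, dtype=float)
        for name in names:
            eff = config.covariates[name]
            mean_s += eff.beta_self * x[name]
            mean_d += eff.beta_delta * x[name]
        cov = np.array([
            [cc.sd_self**2, cc.cov_self_delta],
            [cc.cov_self_delta, cc.sd_delta**2],
        ])
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((n, 2)) @ chol.T
        eta_s = mean_s + z[:, 0]
        delta = mean_d + z[:, 1]
        eta_p = eta_s + delta
        eta_self_all[cname], delta_all[cname], eta_parent_all[cname] = eta_s, delta, eta_p

        lam_p, nu_p = cc.effective_parent_measurement()
        for reporter, eta, lam, nu, sd_e, ths in (
            ("self", eta_s, np.array(cc.loadings_self), np.array(cc.intercepts_self),
             np.array(cc.resid_sd_self), cc.thresholds_self),
            ("parent", eta_p, lam_p, nu_p,
             np.array(cc.resid_sd_parent), cc.thresholds_parent),
        ):
            definition = subscale_definition(cname, reporter)
            eps = rng.standard_normal((n, 5)) * sd_e
            ystar = nu + np.outer(eta, lam) + eps
            for j, col in enumerate(item_columns(cname, reporter)):
                if config.continuous_items:
                    value = ystar[:, j]
                else:
                    t1, t2 = ths[j]
                    value = (ystar[:, j] > t1).astype(int) + (ystar[:, j] > t2).astype(int)
                if definition.reverse_mask[j]:  # emit raw metric
                    value = SDQ_MAX - value
                frame[col] = value

    frame = _attach_k6(frame, x.get("distress"), rng, n)
    frame["sex"] = x.get("sex", np.zeros(n, dtype=int))
    frame["edu"] = x.get("edu", np.zeros(n, dtype=int))
    # the distress screen class equals this binary by construction
    frame["distress"] = x.get("distress", np.zeros(n, dtype=int))
    frame["svywt"] = np.exp(rng.normal(0.0, config.survey_weight_sd, n))
    frame["svywt"] /= frame["svywt"].mean()
    frame["complete"] = 1

    truth = SyntheticTruth(
        config=config, eta_self=eta_self_all, delta=delta_all,
        eta_parent=eta_parent_all, covariate_values=x,
    )
    frame, truth = impose_missingness(frame, config, truth, rng)
    return frame, truth


def _attach_k6(frame: pd.DataFrame, distress: np.ndarray | None, rng, n: int) -> pd.DataFrame:
    """Distress-screen items consistent with the binary distress covariate:
    totals below the cutoff for the low class, at/above for the high class."""
    if distress is None:
        distress = np.zeros(n, dtype=int)
    totals = np.where(
        distress == 1,
        instruments.K6_HIGH_CUTOFF + rng.poisson(3.0, n),
        rng.integers(0, instruments.K6_HIGH_CUTOFF, n),
    )
    totals = np.minimum(totals, 24)
    items = np.zeros((n, 6), dtype=int)
    share = rng.dirichlet(np.ones(6), size=n)
    for i in range(n):
        alloc = np.floor(share[i] * totals[i]).astype(int)
        rem = int(totals[i] - alloc.sum())
        order = np.argsort(-(share[i] * totals[i] - alloc))
        for k in range(rem):
            alloc[order[k % 6]] += 1
        # respect the per-item 0-4 cap by shifting overflow
        for _ in range(10):
            over = alloc > 4
            if not over.any():
                break
            excess = (alloc[over] - 4).sum()
            alloc[over] = 4
            room = np.flatnonzero(alloc < 4)
            for k in range(excess):
                alloc[room[k % len(room)]] += 1
        items[i] = alloc
    for j, col in enumerate(k6_columns()):
        frame[col] = items[:, j]
    return frame


def impose_missingness(
    frame: pd.DataFrame,
    config: GeneratorConfig,
    truth: SyntheticTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth | None]:
    """Unit nonresponse from a logistic model on covariates, then item-level
    MCAR among complete units.  Covariates stay observed throughout."""
    mc = config.missingness
    mc.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(frame)
    logit = np.full(n, mc.logit_intercept, dtype=float)
    for name, coef in mc.logit_coefs.items():
        logit += coef * frame[name].to_numpy()
    p_complete = 1.0 / (1.0 + np.exp(-logit))
    complete = (rng.random(n) < p_complete).astype(int)
    out = frame.copy()
    out["complete"] = complete

    item_cols = [
        c for c in frame.columns
        if any(c.startswith(f"{k}_") for k in CONSTRUCTS) or c.startswith("k6_")
    ]
    mask = pd.DataFrame(False, index=frame.index, columns=item_cols)
    mask.loc[complete == 0, :] = True
    if mc.item_mcar_rate > 0:
        mcar = rng.random((n, len(item_cols))) < mc.item_mcar_rate
        mcar[complete == 0] = True
        mask.loc[:, :] = mcar
    for c in item_cols:
        out[c] = out[c].astype(float)
        out.loc[mask[c].to_numpy(), c] = np.nan
    if truth is not None:
        truth.complete_flag = complete
        truth.item_mask = mask
    return out, truth


# ---------------------------------------------------------------------------
# calibration to target ordinal moments
# ---------------------------------------------------------------------------


def _ordinal_probs_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(P0, P2) of a {0,1,2} variable with the given mean and SD."""
    p2 = (sd**2 + mean**2 - mean) / 2.0
    p0 = 1.0 + p2 - mean
    if not (-1e-9 <= p0 <= 1 + 1e-9 and -1e-9 <= p2 <= 1 + 1e-9 and p0 + p2 <= 1 + 1e-9):
        raise CalibrationError(
            f"targets mean={mean}, sd={sd} infeasible for a 3-point item"
        )
    return float(np.clip(p0, 0, 1)), float(np.clip(p2, 0, 1))


def _mixture_quantile(q: float, means: np.ndarray, sds: np.ndarray, wts: np.ndarray) -> float:
    """Quantile of a normal mixture by bisection on its CDF."""
    if q <= 0.0:
        return -np.inf
    if q >= 1.0:
        return np.inf

    def cdf(t):
        return float(wts @ stats.norm.cdf((t - means) / sds)) - q

    lo = float((means - 8 * sds).min())
    hi = float((means + 8 * sds).max())
    return float(optimize.brentq(cdf, lo, hi, xtol=1e-12))


def _set_thresholds_for_targets(
    cc: ConstructConfig, reporter: str, target_mean: np.ndarray, target_sd: np.ndarray,
    config: GeneratorConfig | None = None,
) -> None:
    """Choose per-item thresholds so the ordinal marginals hit the targets.

    The continuous response marginal is normal (or a normal mixture over
    covariate patterns when ``config`` carries covariate effects), so the
    category probabilities determine the cut points exactly.
    """
    if reporter == "self":
        lam = np.array(cc.loadings_self)
        nu = np.array(cc.intercepts_self)
        sd_e = np.array(cc.resid_sd_self)
    else:
        lam, nu = cc.effective_parent_measurement()
        sd_e = np.array(cc.resid_sd_parent)

    if config is not None and config.covariates:
        names, pats = _covariate_patterns(config)
        b_self = np.array([config.covariates[nm].beta_self for nm in names])
        b_delta = np.array([config.covariates[nm].beta_delta for nm in names])
        wts = np.array([p for _, p in pats])
        shifts = []
        for vals, _ in pats:
            v = np.array(vals, dtype=float)
            if reporter == "self":
                shifts.append(float(b_self @ v))
            else:
                shifts.append(float((b_self + b_delta) @ v))
        shifts = np.array(shifts)
    else:
        wts = np.array([1.0])
        shifts = np.array([0.0])

    if reporter == "self":
        base_mean, base_var = cc.mean_self, cc.sd_self**2
    else:
        base_mean = cc.mean_self + cc.mean_delta
        base_var = cc.sd_self**2 + cc.sd_delta**2 + 2 * cc.cov_self_delta

    out = []
    for j in range(5):
        p0, p2 = _ordinal_probs_from_moments(float(target_mean[j]), float(target_sd[j]))
        mu_mix = nu[j] + lam[j] * (base_mean + shifts)
        sd_mix = np.full_like(mu_mix, np.sqrt(lam[j] ** 2 * base_var + sd_e[j] ** 2))
        t1 = _mixture_quantile(p0, mu_mix, sd_mix, wts)
        t2 = _mixture_quantile(1.0 - p2, mu_mix, sd_mix, wts)
        if not t1 < t2:
            t2 = t1 + 1e-9 if np.isfinite(t1) else t2
        out.append((t1, t2))
    if reporter == "self":
        cc.thresholds_self = out
    else:
        cc.thresholds_parent = out


def calibrate_to_moments(
    targets: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    base: GeneratorConfig | None = None,
) -> GeneratorConfig:
    """Return a config whose ordinal item marginals match the target moments.

    ``targets`` maps (construct, reporter) to (means, sds) arrays of length 5;
    thresholds are solved exactly from the implied continuous marginals.
    """
    if not targets:
        raise CalibrationError("no calibration targets supplied")
    constructs = sorted({c for c, _ in targets})
    if base is None:
        base = default_config(constructs=tuple(constructs))
    cfg = GeneratorConfig(
        n_dyads=base.n_dyads, seed=base.seed,
        constructs={k: v for k, v in base.constructs.items()},
        covariates=dict(base.covariates), missingness=base.missingness,
        survey_weight_sd=base.survey_weight_sd,
    )
    for (construct, reporter), (mean, sd) in targets.items():
        if construct not in cfg.constructs:
            cfg.constructs[construct] = default_construct_config(construct)
        _set_thresholds_for_targets(
            cfg.constructs[construct], reporter,
            np.asarray(mean, dtype=float), np.asarray(sd, dtype=float),
            config=cfg,
        )
    cfg.validate()
    return cfg


def write_dyads_csv(frame: pd.DataFrame, path) -> None:
    """Byte-stable CSV writer (fixed float format, blank for missing)."""
    frame.to_csv(path, index=False, float_format="%.10g", na_rep="")


def dyad_records(frame: pd.DataFrame, constructs=None) -> list[instruments.DyadRecord]:
    """View a dyad frame as typed records (raw item metric)."""
    constructs = constructs or [
        c for c in CONSTRUCTS if item_columns(c, "self")[0] in frame.columns
    ]
    records = []
    for _, row in frame.iterrows():
        records.append(instruments.DyadRecord(
            dyad_id=int(row["dyad_id"]) if "dyad_id" in row else -1,
            self_items={c: [row[col] for col in item_columns(c, "self")] for c in constructs},
            parent_items={c: [row[col] for col in item_columns(c, "parent")] for c in constructs},
            distress_items=[row[col] for col in k6_columns()],
            sex=int(row["sex"]), education=int(row["edu"]),
            survey_weight=float(row["svywt"]), complete=bool(row["complete"]),
        ))
    return records
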
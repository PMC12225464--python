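"""Two-stage conditional Bernoulli likelihood with logit submodels.

The observation model for a patrol outcome y is

    y ~ Bernoulli(p * s),   s ~ Bernoulli(v),

where v is the probability that a violation is present in the context of the
patrol and p the probability of detecting it given that it is present.  Both
probabilities are logistic regressions: effort (scaled patrol time, scaled
group size), actor, region and year drive detection; violation type and
species drive violation occurrence.  Marginalising the latent indicator s
gives P(y=1) = v*p and P(y=0) = 1 - v*p, which is what the inference code
uses; latent simulation is available for equivalence checks.

All coefficients carry flat bounded priors on [-2.2, 2.2] (log-odds of about
-90% to +90%), with each factor's reference level fixed at zero.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .records import CategoryScheme, Design, FACTORS

#: Half-width of the flat prior box on every coefficient (log-odds scale).
PRIOR_BOUND = 2.2

_NAME_RE = re.compile(r"^(\w+)\[(.+)\]$")


@dataclass
class ModelParameters:
    """Log-odds-scale parameters of the two submodels.

    ``effects`` maps factor name -> {level: coefficient}; reference levels are
    fixed at exactly 0 and need not be listed.
    """

    mu_p: float = 0.0
    mu_v: float = 0.0
    b_time: float = 0.0
    b_enforcers: float = 0.0
    effects: dict = field(default_factory=dict)

    def effect(self, factor: str, level) -> float:
        return float(self.effects.get(factor, {}).get(level, 0.0))

    def validate(self, scheme: CategoryScheme | None = None) -> None:
        vals = [self.mu_p, self.mu_v, self.b_time, self.b_enforcers]
        for factor, d in self.effects.items():
            if factor not in FACTORS:
                raise ValueError(f"unknown factor {factor!r} in effects")
            vals.extend(d.values())
            if scheme is not None:
                ref = scheme.reference(factor)
                if d.get(ref, 0.0) != 0.0:
                    raise ValueError(f"reference level {ref!r} of {factor!r} must have effect 0")
                unknown = set(d) - set(scheme.levels(factor))
                if unknown:
                    raise ValueError(f"effects reference unknown level(s) {unknown!r} of {factor!r}")
        if any(abs(v) > PRIOR_BOUND for v in vals):
            raise ValueError(f"coefficient outside the prior box [-{PRIOR_BOUND}, {PRIOR_BOUND}]")

    # -- vector interface (parameter order defined by a Design) -------------
    def to_vector(self, design: Design) -> np.ndarray:
        return np.array([self._lookup(nm) for nm in design.param_names], dtype=float)

    def _lookup(self, name: str) -> float:
        if name == "mu_p":
            return self.mu_p
        if name == "mu_v":
            return self.mu_v
        if name == "time":
            return self.b_time
        if name == "enforcers":
            return self.b_enforcers
        m = _NAME_RE.match(name)
        if m is None:
            raise ValueError(f"unparseable parameter name {name!r}")
        factor, level = m.groups()
        if factor == "year":
            level = int(level)
        return self.effect(factor, level)

    @classmethod
    def from_vector(cls, vec: np.ndarray, param_names: list[str]) -> "ModelParameters":
        params = cls()
        for nm, val in zip(param_names, vec):
            val = float(val)
            if nm == "mu_p":
                params.mu_p = val
            elif nm == "mu_v":
                params.mu_v = val
            elif nm == "time":
                params.b_time = val
            elif nm == "enforcers":
                params.b_enforcers = val
            else:
                m = _NAME_RE.match(nm)
                if m is None:
                    raise ValueError(f"unparseable parameter name {nm!r}")
                factor, level = m.groups()
                if factor == "year":
                    level = int(level)
                params.effects.setdefault(factor, {})[level] = val
        return params

    # -- JSON (keyed by level names, portable across schemes) ---------------
    def to_json(self, path) -> None:
        doc = {
            "mu_p": self.mu_p,
            "mu_v": self.mu_v,
            "b_time": self.b_time,
            "b_enforcers": self.b_enforcers,
            "effects": {f: {str(k): v for k, v in d.items()} for f, d in self.effects.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            doc = json.load(fh)
        effects = {
            f: {(int(k) if f == "year" else k): float(v) for k, v in d.items()}
            for f, d in doc.pop("effects", {}).items()
        }
        return cls(effects=effects, **doc)


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------

def _split_vector(vec: np.ndarray, design: Design):
    k_det = len(design.det_names)
    mu_p = vec[0]
    beta_det = vec[1 : 1 + k_det]
    mu_v = vec[1 + k_det]
    beta_viol = vec[2 + k_det :]
    return mu_p, beta_det, mu_v, beta_viol


def detection_logit(design: Design, params) -> np.ndarray:
    """Linear predictor of detectability, one value per record."""
    vec = params.to_vector(design) if isinstance(params, ModelParameters) else np.asarray(params)
    mu_p, beta_det, _, _ = _split_vector(vec, design)
    return mu_p + design.X_det @ beta_det


def violation_logit(design: Design, params) -> np.ndarray:
    """Linear predictor of violation occurrence, one value per record."""
    vec = params.to_vector(design) if isinstance(params, ModelParameters) else np.asarray(params)
    _, _, mu_v, beta_viol = _split_vector(vec, design)
    return mu_v + design.X_viol @ beta_viol


def detection_probability(design: Design, params) -> np.ndarray:
    return expit(detection_logit(design, params))


def violation_probability(design: Design, params) -> np.ndarray:
    return expit(violation_logit(design, params))


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def marginal_observation_probability(v, p, y):
    """P(y | v, p) with the latent violation indicator summed out.

    P(y=1) = v*p (a violation occurs with probability v, and is then detected
    with probability p); P(y=0) = 1 - v*p.
    """
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if ((v < 0) | (v > 1)).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("v and p must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary")
    vp = v * p
    out = np.where(y == 1, vp, 1.0 - vp)
    return float(out) if out.ndim == 0 else out


def log_marginal_observation_probability(v, p, y):
    """Log of :func:`marginal_observation_probability`, stable near 0 and 1.

    For y=1 the log factors as log v + log p; for y=0 it uses log1p(-v*p).
    """
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if ((v < 0) | (v > 1)).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("v and p must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_vp = np.log(v) + np.log(p)
    out = np.where(y == 1, log_vp, np.log1p(-v * p))
    return float(out) if out.ndim == 0 else out


def pointwise_loglik(vec: np.ndarray, design: Design) -> np.ndarray:
    """Per-record log-likelihood at a parameter vector."""
    p = expit(detection_logit(design, vec))
    v = expit(violation_logit(design, vec))
    return log_marginal_observation_probability(v, p, design.y)


def log_prior(params) -> float:
    """Flat box prior: 0 inside the closed box [-2.2, 2.2]^K, -inf outside.

    Reference-level zeros carry no prior dimension.
    """
    if isinstance(params, ModelParameters):
        vals = [params.mu_p, params.mu_v, params.b_time, params.b_enforcers]
        for d in params.effects.values():
            vals.extend(d.values())
        vec = np.array(vals, dtype=float)
    else:
        vec = np.asarray(params, dtype=float)
    return 0.0 if np.all(np.abs(vec) <= PRIOR_BOUND) else -np.inf


def log_posterior(params, design: Design) -> float:
    """Unnormalised log posterior: sum of record log-likelihoods plus the box prior."""
    lp = log_prior(params)
    if not np.isfinite(lp):
        return -np.inf
    vec = params.to_vector(design) if isinstance(params, ModelParameters) else np.asarray(params)
    return lp + float(pointwise_loglik(vec, design).sum())


def simulate_outcomes(vec_or_params, design: Design, rng: np.random.Generator):
    """Draw (s, y) from the generative two-stage process — the latent-sampling
    route, used for equivalence checks against the marginalised likelihood."""
    vec = (
        vec_or_params.to_vector(design)
        if isinstance(vec_or_params, ModelParameters)
        else np.asarray(vec_or_params)
    )
    p = expit(detection_logit(design, vec))
    v = expit(violation_logit(design, vec))
    s = rng.random(design.n_records) < v
    y = (rng.random(design.n_records) < p) & s
    return s.astype(int), y.astype(int)
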
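"""One order's perception-action cycle.

A FEP unit perceives its niche (a hidden true state), infers a posterior
over hidden states, scores the three candidate policies by expected free
energy, acts, and carries its posterior forward as the next prior. Its
variational free energy after each observation quantifies the total
prediction error of that step, and is what the unit broadcasts to its
sibling orders.

All free energies are in nats (natural logarithm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .generative_model import N_POLICIES, GenerativeModel, OrderLabel

__all__ = [
    "EPS",
    "FepUnit",
    "Environment",
    "StepRecord",
    "infer_state",
    "expected_states",
    "expected_obs",
    "efe_components",
    "expected_free_energy",
    "select_policy",
    "variational_free_energy",
    "unit_step",
    "run_unit",
]

#: floor applied inside every logarithm
EPS = 1e-16

#: numerical tie width for policy selection: expected-free-energy values
#: closer than this are treated as exact ties (broken toward the lowest
#: policy index), so floor-level noise cannot flip a degenerate choice
TIE_ATOL = 1e-12

ACTION_NAMES = ("up", "down", "stay")


def _log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, EPS))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max())
    return z / z.sum()


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    # 0 * log 0 = 0 convention; both arguments floored inside the log
    return float(np.sum(p * (_log(p) - _log(q))))


def _entropy(p: np.ndarray) -> float:
    return float(-np.sum(p * _log(p)))


@dataclass
class Environment:
    """The niche of one unit: a hidden true state on the discrete line."""

    true_state: int
    n_states: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.true_state < self.n_states:
            raise ValueError(
                f"true_state {self.true_state} out of range [0, {self.n_states})"
            )


@dataclass
class FepUnit:
    """Mutable inferential state of one order."""

    model: GenerativeModel
    prior: np.ndarray = None  # type: ignore[assignment]
    posterior: np.ndarray = None  # type: ignore[assignment]
    last_observation: int | None = None
    last_action: int | None = None
    current_F: float = 0.0
    current_G: np.ndarray = field(
        default_factory=lambda: np.zeros(N_POLICIES)
    )

    def __post_init__(self) -> None:
        if self.prior is None:
            self.prior = self.model.D.copy()
        if self.posterior is None:
            self.posterior = np.full(
                self.model.n_states, 1.0 / self.model.n_states
            )


@dataclass
class StepRecord:
    """Everything one unit did at one time step."""

    t: int
    agent_id: str
    order: OrderLabel
    true_state: int
    observation: int
    map_state: int
    posterior: np.ndarray
    F: float
    G: np.ndarray
    action: int

    def with_context(self, t: int, agent_id: str, order: OrderLabel) -> "StepRecord":
        return replace(self, t=t, agent_id=agent_id, order=order)


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------


def infer_state(
    model: GenerativeModel, o: int, prior: np.ndarray
) -> np.ndarray:
    """Posterior over hidden states given observation ``o``.

    Computes ``softmax(log A[o, :] + log prior)``, which is exactly the
    normalized Bayes posterior ``P(s | o) \\propto A[o, s] * prior(s)``
    (up to the floor applied to zeros before the logarithms).
    """
    if not 0 <= o < model.n_states:
        raise IndexError(f"observation {o} out of range [0, {model.n_states})")
    return _softmax(_log(model.A[o, :]) + _log(prior))


def variational_free_energy(
    model: GenerativeModel, q: np.ndarray, o: int, prior: np.ndarray
) -> float:
    """Variational free energy of belief ``q`` after observing ``o``.

    ``F = KL(q || normalize(A[o, :])) - log P(o)`` with
    ``P(o) = sum_s A[o, s] * prior(s)``. The KL term measures the error in
    state estimation against the likelihood column, the evidence term the
    surprise of the observation itself; for a uniform prior the sum equals
    the negative evidence lower bound.
    """
    if not 0 <= o < model.n_states:
        raise IndexError(f"observation {o} out of range [0, {model.n_states})")
    likelihood_col = model.A[o, :]
    lik_norm = likelihood_col / max(likelihood_col.sum(), EPS)
    log_evidence = float(np.log(max(float(likelihood_col @ prior), EPS)))
    return _kl(q, lik_norm) - log_evidence


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------


def expected_states(
    model: GenerativeModel, q: np.ndarray, policy: int
) -> np.ndarray:
    """Predicted state distribution one step ahead under ``policy``."""
    return model.B[:, :, policy] @ q


def expected_obs(model: GenerativeModel, qs: np.ndarray) -> np.ndarray:
    """Predicted observation distribution for state beliefs ``qs``."""
    return model.A @ qs


def efe_components(
    model: GenerativeModel, q: np.ndarray, policy: int
) -> tuple[float, float]:
    """Ambiguity and risk terms of the expected free energy of ``policy``.

    ambiguity = sum_s qs(s) * H(A[:, s])   (expected observation entropy)
    risk      = KL( A @ qs || C )          (predicted obs vs preference)
    """
    qs = expected_states(model, q, policy)
    ambiguity = float(
        sum(qs[s] * _entropy(model.A[:, s]) for s in range(model.n_states))
    )
    risk = _kl(expected_obs(model, qs), model.C)
    return ambiguity, risk


def expected_free_energy(
    model: GenerativeModel, q: np.ndarray, policy: int
) -> float:
    """Expected free energy ``G(policy) = ambiguity + risk`` (>= 0)."""
    ambiguity, risk = efe_components(model, q, policy)
    return ambiguity + risk


def select_policy(
    G_values: np.ndarray,
    rng: np.random.Generator | None = None,
    temperature: float | None = None,
) -> int:
    """Pick the policy with minimal expected free energy.

    Default is a hard argmin; values within ``TIE_ATOL`` of the minimum are
    treated as tied and the lowest policy index wins, so the choice is
    deterministic. When ``temperature`` is given, a policy is instead
    sampled from ``softmax(-G / temperature)`` using ``rng``.
    """
    G = np.asarray(G_values, dtype=float)
    if G.shape != (N_POLICIES,) or not np.all(np.isfinite(G)):
        raise ValueError(f"need {N_POLICIES} finite G values, got {G_values!r}")
    if temperature is not None:
        if rng is None:
            raise ValueError("softmax policy selection needs an rng")
        p = _softmax(-G / temperature)
        return int(rng.choice(N_POLICIES, p=p))
    return int(np.argmax(G <= G.min() + TIE_ATOL))


# ---------------------------------------------------------------------------
# the full step
# ---------------------------------------------------------------------------


def unit_step(
    unit: FepUnit,
    env: Environment,
    external_log_prior_adjustment: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> StepRecord:
    """Run one complete perception-action cycle, mutating unit and env.

    Sub-step order: (a) sample the observation from the likelihood column of
    the true state; (b) tilt the prior by the external log-prior adjustment
    (messages from sibling orders; zeros when uncoupled); (c) infer the
    posterior; (d) score the variational free energy; (e) score all three
    policies by expected free energy; (f) select the action; (g) advance the
    niche's true state through the chosen transition; (h) propagate the
    posterior through that transition to form the next prior.

    ``deterministic=True`` replaces observation sampling with the argmax of
    the likelihood column; the rest of the cycle is deterministic anyway.
    """
    model = unit.model
    n = model.n_states
    s_star = env.true_state

    # (a) observe
    lik_col = model.A[:, s_star]
    if deterministic:
        o = int(np.argmax(lik_col))
    else:
        if rng is None:
            raise ValueError("stochastic observation sampling needs an rng")
        o = int(rng.choice(n, p=lik_col / lik_col.sum()))

    # (b) external message tilt in log-prior space
    if external_log_prior_adjustment is None:
        adjusted_prior = unit.prior
    else:
        adj = np.asarray(external_log_prior_adjustment, dtype=float)
        if adj.shape != (n,):
            raise ValueError(
                f"adjustment has shape {adj.shape}, expected {(n,)}"
            )
        if np.any(adj != 0.0):
            adjusted_prior = _softmax(_log(unit.prior) + adj)
        else:
            adjusted_prior = unit.prior

    # (c) infer, (d) prediction error
    posterior = infer_state(model, o, adjusted_prior)
    F = variational_free_energy(model, posterior, o, adjusted_prior)

    # (e) plan, (f) act
    G = np.array(
        [expected_free_energy(model, posterior, pi) for pi in range(N_POLICIES)]
    )
    action = select_policy(G)

    # (g) the niche responds: deterministic transition of the true state
    env.true_state = int(np.argmax(model.B[:, s_star, action]))

    # (h) predict forward: posterior propagated through the chosen transition
    unit.prior = model.B[:, :, action] @ posterior
    unit.posterior = posterior
    unit.last_observation = o
    unit.last_action = action
    unit.current_F = F
    unit.current_G = G

    return StepRecord(
        t=-1,
        agent_id="",
        order=OrderLabel.REAL,
        true_state=s_star,
        observation=o,
        map_state=int(np.argmax(posterior)),
        posterior=posterior.copy(),
        F=F,
        G=G.copy(),
        action=action,
    )


def run_unit(
    model: GenerativeModel,
    initial_state: int,
    steps: int,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> list[StepRecord]:
    """Run a single uncoupled unit for ``steps`` cycles from ``initial_state``."""
    unit = FepUnit(model=model.copy())
    env = Environment(true_state=initial_state, n_states=model.n_states)
    records = []
    for t in range(steps):
        rec = unit_step(unit, env, None, rng, deterministic)
        records.append(replace(rec, t=t))
    return records
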
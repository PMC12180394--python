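"""One agent as three coupled FEP units: Real, Symbolic, Imaginary.

The three orders are computationally equivalent inference units, each with
its own niche, coupled by precision-weighted message passing of prediction
errors: after every step each order broadcasts its posterior's deviation
from the uniform belief, scaled by its precision weight and by its current
variational free energy, and each order's prior is tilted (in log space) by
the sum of the two sibling messages before the next inference. A weight of
zero silences an order entirely, so the uncoupled agent factorizes exactly
into three independent units; larger weights propagate a perturbation in
one order more strongly into the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .generative_model import (
    GenerativeModel,
    OrderLabel,
    make_default_model,
)
from .fep_unit import Environment, FepUnit, unit_step
from .metrics import ORDERS, Trajectory

__all__ = [
    "CouplingWeights",
    "RsiAgent",
    "IndividualConfig",
    "compute_messages",
    "agent_step",
    "make_order_rngs",
    "build_agent",
    "run_individual",
]

#: stream tags for deterministic per-(agent, order) rng splitting; the
#: fourth stream feeds an agent's desire observations in multi-agent runs
_STREAM_TAGS = {
    OrderLabel.REAL: 0,
    OrderLabel.SYMBOLIC: 1,
    OrderLabel.IMAGINARY: 2,
}
DESIRE_STREAM_TAG = 3


@dataclass
class CouplingWeights:
    """Per-order precision weights scaling each order's outgoing messages."""

    real: float = 0.0
    symbolic: float = 0.0
    imaginary: float = 0.0

    def __post_init__(self) -> None:
        for name in ("real", "symbolic", "imaginary"):
            if getattr(self, name) < 0:
                raise ValueError(f"coupling weight {name} must be >= 0")

    def __getitem__(self, order: OrderLabel) -> float:
        return {
            OrderLabel.REAL: self.real,
            OrderLabel.SYMBOLIC: self.symbolic,
            OrderLabel.IMAGINARY: self.imaginary,
        }[order]

    @classmethod
    def uniform(cls, w: float) -> "CouplingWeights":
        return cls(real=w, symbolic=w, imaginary=w)

    def to_dict(self) -> dict:
        return {
            "real": self.real,
            "symbolic": self.symbolic,
            "imaginary": self.imaginary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingWeights":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class RsiAgent:
    """Three labeled units, their three niches, and the coupling weights."""

    agent_id: str
    units: dict
    envs: dict
    weights: CouplingWeights

    def __post_init__(self) -> None:
        sizes = {self.units[o].model.n_states for o in ORDERS}
        if len(sizes) != 1:
            raise ValueError(f"units of {self.agent_id} disagree on n_states")

    @property
    def n_states(self) -> int:
        return self.units[OrderLabel.REAL].model.n_states


def compute_messages(agent: RsiAgent) -> dict:
    """Outgoing message of each order from its last completed step.

    ``m_k = w_k * F_k * (q_k - 1/n)``: the sender's posterior deviation from
    the uniform belief, scaled by its precision-weighted prediction error.
    Every message sums to zero, so receiving priors stay normalizable. At
    t=0 the posterior is uniform and F is zero, so all messages vanish.
    """
    n = agent.n_states
    messages = {}
    for order in ORDERS:
        unit = agent.units[order]
        w = agent.weights[order]
        messages[order] = w * unit.current_F * (unit.posterior - 1.0 / n)
    return messages


def agent_step(
    agent: RsiAgent,
    rngs: dict | None = None,
    deterministic: bool = False,
) -> dict:
    """Advance all three orders by one step with synchronous message passing.

    Messages are computed from every unit's previous-step posterior and F
    *before* any unit moves, so the result does not depend on the order in
    which the units are stepped. Each order receives the *average* of the
    other orders' messages as its log-prior adjustment; averaging (rather
    than summing) normalizes the received tilt by the number of senders, so
    the coupling stays in the sensitive range of action selection across
    the whole 0-2 weight span instead of saturating it.
    """
    messages = compute_messages(agent)
    records = {}
    for order in ORDERS:
        adjustment = np.mean(
            [messages[k] for k in ORDERS if k is not order], axis=0
        )
        rng = None if rngs is None else rngs[order]
        rec = unit_step(
            agent.units[order],
            agent.envs[order],
            adjustment,
            rng,
            deterministic,
        )
        records[order] = replace(rec, agent_id=agent.agent_id, order=order)
    return records


def make_order_rngs(seed: int, agent_index: int = 0) -> dict:
    """Independent, reproducible random streams for one agent.

    Streams are keyed by (master seed, agent index, stream tag), so each
    (agent, order) pair owns a fixed stream regardless of how many agents a
    scenario contains: adding or removing agents, or removing desire edges,
    never perturbs anyone else's randomness. Tag 3 is reserved for the
    agent's desire-observation stream.
    """
    rngs = {
        order: np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(agent_index, tag))
        )
        for order, tag in _STREAM_TAGS.items()
    }
    rngs["desire"] = np.random.default_rng(
        np.random.SeedSequence(
            entropy=seed, spawn_key=(agent_index, DESIRE_STREAM_TAG)
        )
    )
    return rngs


# ---------------------------------------------------------------------------
# the individual perturbation protocol
# ---------------------------------------------------------------------------


@dataclass
class IndividualConfig:
    """Configuration of a single-agent run with a Symbolic perturbation.

    The default protocol perturbs the Symbolic order by starting its niche
    at state 1 while giving it a sharp preference for observation 4; the
    Real and Imaginary orders start at the center of the state line with
    uniform (indifferent) preferences.
    """

    n_states: int = 5
    likelihood_noise: float = 0.2
    weights: CouplingWeights = field(default_factory=CouplingWeights)
    steps: int = 15
    perturbed_order: OrderLabel = OrderLabel.SYMBOLIC
    perturb_initial_state: int = 1
    perturb_preferred_obs: int | None = 4
    preference_sharpness: float = 4.0
    baseline_state: int = 2
    deterministic: bool = False

    def unperturbed(self) -> "IndividualConfig":
        """The matched baseline: same run with the perturbation removed."""
        return replace(
            self,
            perturb_initial_state=self.baseline_state,
            perturb_preferred_obs=None,
        )

    # -- JSON round trip ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "likelihood_noise": self.likelihood_noise,
            "weights": self.weights.to_dict(),
            "steps": self.steps,
            "perturbation": {
                "order": self.perturbed_order.value,
                "initial_state": self.perturb_initial_state,
                "preferred_obs": self.perturb_preferred_obs,
                "sharpness": self.preference_sharpness,
            },
            "baseline_state": self.baseline_state,
            "deterministic": self.deterministic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndividualConfig":
        kwargs: dict = {}
        for key in ("n_states", "likelihood_noise", "steps", "baseline_state",
                    "deterministic"):
            if key in d:
                kwargs[key] = d[key]
        if "weights" in d:
            kwargs["weights"] = CouplingWeights.from_dict(d["weights"])
        pert = d.get("perturbation", {})
        if "order" in pert:
            kwargs["perturbed_order"] = OrderLabel(pert["order"])
        if "initial_state" in pert:
            kwargs["perturb_initial_state"] = pert["initial_state"]
        if "preferred_obs" in pert:
            kwargs["perturb_preferred_obs"] = pert["preferred_obs"]
        if "sharpness" in pert:
            kwargs["preference_sharpness"] = pert["sharpness"]
        return cls(**kwargs)


def _order_model(config: IndividualConfig, order: OrderLabel) -> GenerativeModel:
    if order is config.perturbed_order and config.perturb_preferred_obs is not None:
        return make_default_model(
            n_states=config.n_states,
            likelihood_noise=config.likelihood_noise,
            preferred_obs=config.perturb_preferred_obs,
            preference_sharpness=config.preference_sharpness,
        )
    return make_default_model(
        n_states=config.n_states,
        likelihood_noise=config.likelihood_noise,
        preferred_obs=None,
    )


def build_agent(config: IndividualConfig, agent_id: str = "A") -> RsiAgent:
    """Materialize one agent (units + niches) from a configuration."""
    units, envs = {}, {}
    for order in ORDERS:
        model = _order_model(config, order)
        initial = (
            config.perturb_initial_state
            if order is config.perturbed_order
            else config.baseline_state
        )
        units[order] = FepUnit(model=model)
        envs[order] = Environment(true_state=initial, n_states=config.n_states)
    return RsiAgent(
        agent_id=agent_id, units=units, envs=envs, weights=config.weights
    )


def run_individual(
    config: IndividualConfig,
    seed: int,
    agent_id: str = "A",
    agent_index: int = 0,
) -> Trajectory:
    """Run the single-agent protocol and return the full trajectory."""
    agent = build_agent(config, agent_id)
    rngs = make_order_rngs(seed, agent_index)
    traj = Trajectory(agent_id=agent_id, n_states=config.n_states)
    for t in range(config.steps):
        records = agent_step(agent, rngs, config.deterministic)
        for order in ORDERS:
            traj.records.append(replace(records[order], t=t))
    return traj
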
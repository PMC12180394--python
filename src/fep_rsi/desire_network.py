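"""Multi-agent desire networks.

Desire is modeled as preference inference about another agent: a desirer
observes the desired agent's public Symbolic state through its *own*
Symbolic likelihood, infers a posterior over that state, and installs the
posterior as its own Symbolic preference for the next step. In a dyad both
agents desire each other (mutual preference inference); in a triad the
desire edges form a directed ring A -> B -> C -> A. Agents never exchange
messages directly — every inter-agent influence flows through this
preference channel, so removing all desire edges reproduces independent
solo runs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .generative_model import OrderLabel
from .fep_unit import EPS, infer_state
from .metrics import (
    DEFAULT_SYNC_WINDOW,
    ORDERS,
    SyncReport,
    Trajectory,
    divergence,
    free_energy_totals,
    sync_index,
)
from .rsi_agent import (
    CouplingWeights,
    IndividualConfig,
    RsiAgent,
    agent_step,
    build_agent,
    make_order_rngs,
)

__all__ = [
    "DesireGraph",
    "NetworkConfig",
    "desire_update",
    "run_network",
    "run_dyad",
    "run_triad",
]


@dataclass
class DesireGraph:
    """Directed "who desires whom" structure among named agents."""

    agents: list[str]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        known = set(self.agents)
        outgoing: dict[str, int] = {}
        for desirer, desired in self.edges:
            if desirer == desired:
                raise ValueError(f"self-desire edge {desirer!r} not allowed")
            if desirer not in known or desired not in known:
                raise ValueError(
                    f"edge ({desirer!r}, {desired!r}) references unknown agent"
                )
            outgoing[desirer] = outgoing.get(desirer, 0) + 1
            if outgoing[desirer] > 1:
                raise ValueError(
                    f"agent {desirer!r} has more than one outgoing desire edge"
                )

    @classmethod
    def mutual_pair(cls, a: str = "A", b: str = "B") -> "DesireGraph":
        return cls(agents=[a, b], edges=[(a, b), (b, a)])

    @classmethod
    def ring(cls, agents: tuple[str, str, str] = ("A", "B", "C")) -> "DesireGraph":
        a, b, c = agents
        return cls(agents=list(agents), edges=[(a, b), (b, c), (c, a)])


def desire_update(
    desirer: RsiAgent,
    desired: RsiAgent,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
) -> np.ndarray:
    """Install the desirer's inference of another's Symbolic state as its
    own Symbolic preference.

    The desired agent's Symbolic niche state is read through the desirer's
    own Symbolic likelihood (an observation is sampled from that likelihood
    column, or taken as its argmax in deterministic mode), a posterior is
    inferred under a uniform prior, and the floored, renormalized posterior
    becomes the desirer's Symbolic C. Returns the new preference vector.
    """
    unit = desirer.units[OrderLabel.SYMBOLIC]
    model = unit.model
    n = model.n_states
    if desired.n_states != n:
        raise ValueError(
            f"agents {desirer.agent_id!r} and {desired.agent_id!r} live in "
            f"different state spaces ({n} vs {desired.n_states})"
        )
    desired_symbolic_state = desired.envs[OrderLabel.SYMBOLIC].true_state
    lik_col = model.A[:, desired_symbolic_state]
    if deterministic:
        o = int(np.argmax(lik_col))
    else:
        if rng is None:
            raise ValueError("stochastic desire observation needs an rng")
        o = int(rng.choice(n, p=lik_col / lik_col.sum()))
    posterior = infer_state(model, o, np.full(n, 1.0 / n))
    new_c = np.maximum(posterior, EPS)
    new_c = new_c / new_c.sum()
    model.C = new_c
    return new_c


@dataclass
class NetworkConfig:
    """Shared configuration of a multi-agent run.

    All agents carry identical internal models (same state space, noise and
    internal coupling weights) and differ only in their initial Symbolic
    niche states. Real and Imaginary niches start at the center of the
    state line with indifferent preferences; Symbolic preferences are
    uniform until the first desire update overwrites them.
    """

    n_states: int = 5
    likelihood_noise: float = 0.2
    weights: CouplingWeights = field(
        default_factory=lambda: CouplingWeights.uniform(1.5)
    )
    steps: int = 15
    initial_symbolic_states: tuple[int, ...] = (0, 4)
    baseline_state: int = 2
    deterministic: bool = False
    desire_enabled: bool = True
    sync_window: int = DEFAULT_SYNC_WINDOW

    def agent_config(self, agent_index: int) -> IndividualConfig:
        return IndividualConfig(
            n_states=self.n_states,
            likelihood_noise=self.likelihood_noise,
            weights=self.weights,
            steps=self.steps,
            perturbed_order=OrderLabel.SYMBOLIC,
            perturb_initial_state=self.initial_symbolic_states[agent_index],
            perturb_preferred_obs=None,
            baseline_state=self.baseline_state,
            deterministic=self.deterministic,
        )

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "likelihood_noise": self.likelihood_noise,
            "weights": self.weights.to_dict(),
            "steps": self.steps,
            "initial_symbolic_states": list(self.initial_symbolic_states),
            "baseline_state": self.baseline_state,
            "deterministic": self.deterministic,
            "desire_enabled": self.desire_enabled,
            "sync_window": self.sync_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        kwargs = {
            k: d[k]
            for k in (
                "n_states", "likelihood_noise", "steps", "baseline_state",
                "deterministic", "desire_enabled", "sync_window",
            )
            if k in d
        }
        if "weights" in d:
            kwargs["weights"] = CouplingWeights.from_dict(d["weights"])
        if "initial_symbolic_states" in d:
            kwargs["initial_symbolic_states"] = tuple(
                d["initial_symbolic_states"]
            )
        return cls(**kwargs)


def run_network(
    config: NetworkConfig, graph: DesireGraph, seed: int
) -> list[Trajectory]:
    """Run any desire network for ``config.steps`` synchronous steps.

    Every step, first all desire edges fire (each desirer re-infers its
    preference from the desired agent's Symbolic state as of the *previous*
    step), then all agents advance; neither phase depends on agent order.
    """
    if len(graph.agents) != len(config.initial_symbolic_states):
        raise ValueError(
            f"{len(graph.agents)} agents but "
            f"{len(config.initial_symbolic_states)} initial Symbolic states"
        )
    agents = {
        name: build_agent(config.agent_config(i), agent_id=name)
        for i, name in enumerate(graph.agents)
    }
    rngs = {
        name: make_order_rngs(seed, agent_index=i)
        for i, name in enumerate(graph.agents)
    }
    edges = list(graph.edges) if config.desire_enabled else []
    trajectories = {
        name: Trajectory(agent_id=name, n_states=config.n_states)
        for name in graph.agents
    }

    for t in range(config.steps):
        # desire updates read last-step niche states and only touch C, so
        # running them all before any agent moves keeps the phase synchronous
        for desirer, desired in edges:
            desire_update(
                agents[desirer],
                agents[desired],
                rngs[desirer]["desire"],
                config.deterministic,
            )
        for name in graph.agents:
            records = agent_step(agents[name], rngs[name], config.deterministic)
            for order in ORDERS:
                trajectories[name].records.append(
                    replace(records[order], t=t)
                )
    return [trajectories[name] for name in graph.agents]


def _pairwise_sync(
    trajectories: list[Trajectory], window: tuple[int, int]
) -> SyncReport:
    report = SyncReport(window=window)
    for i, ta in enumerate(trajectories):
        for tb in trajectories[i + 1:]:
            report.pairs[(ta.agent_id, tb.agent_id)] = {
                order.value: sync_index(ta, tb, order, window)
                for order in ORDERS
            }
    return report


def run_dyad(
    config: NetworkConfig | None = None, seed: int = 0
) -> tuple[list[Trajectory], dict]:
    """Two agents in mutual desire; returns trajectories and metrics.

    The metrics report per-order synchronization indices over the final
    window and over the whole run, plus per-agent free-energy totals.
    """
    config = config or NetworkConfig()
    graph = DesireGraph.mutual_pair()
    trajectories = run_network(config, graph, seed)
    final = (config.steps - config.sync_window, config.steps)
    report = {
        "sync_final_window": _pairwise_sync(trajectories, final).to_dict(),
        "sync_full_run": _pairwise_sync(
            trajectories, (0, config.steps)
        ).to_dict(),
        "free_energy_totals": free_energy_totals(trajectories),
    }
    return trajectories, report


def run_triad(
    config: NetworkConfig | None = None,
    seed: int = 0,
    sensitivity_probe: bool = True,
) -> tuple[list[Trajectory], dict]:
    """Three agents in the directed desire ring A -> B -> C -> A.

    Besides pairwise synchronization indices, the report optionally carries
    a divergence-sensitivity probe: the same run is repeated with agent A's
    initial Symbolic state shifted by one, and the per-step mean absolute
    state difference between the two runs is reported.
    """
    if config is None:
        config = NetworkConfig(initial_symbolic_states=(0, 2, 4))
    graph = DesireGraph.ring()
    trajectories = run_network(config, graph, seed)
    final = (config.steps - config.sync_window, config.steps)
    report = {
        "sync_final_window": _pairwise_sync(trajectories, final).to_dict(),
        "sync_full_run": _pairwise_sync(
            trajectories, (0, config.steps)
        ).to_dict(),
        "free_energy_totals": free_energy_totals(trajectories),
    }
    if sensitivity_probe:
        states = list(config.initial_symbolic_states)
        states[0] = states[0] + 1 if states[0] + 1 < config.n_states else states[0] - 1
        probe_config = replace(
            config, initial_symbolic_states=tuple(states)
        )
        probe = run_network(probe_config, graph, seed)
        series, final_mean = divergence(
            trajectories, probe, final_window=config.sync_window
        )
        report["divergence_sensitivity"] = {
            "perturbed_initial_symbolic_states": states,
            "series": [float(x) for x in series],
            "final_window_mean": final_mean,
        }
    return trajectories, report
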
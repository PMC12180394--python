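"""Discrete generative models for FEP units.

Each inference unit ("order") holds a generative model of its niche in the
standard discrete active-inference form:

* ``A`` — likelihood matrix, ``A[o, s] = P(o | s)``; the observation alphabet
  equals the hidden-state alphabet (square A).
* ``B`` — transition tensor, ``B[s', s, pi] = P(s' | s, pi)`` for the three
  single-step policies *move up* (``s+1``), *move down* (``s-1``) and *stay*.
* ``C`` — preference distribution over observations (a simplex).
* ``D`` — prior belief over hidden states (a simplex).

States live on a bounded line ``0 .. n_states-1``; the move policies clamp at
the boundaries rather than wrapping, so the state space has edges, not a ring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATOL",
    "OrderLabel",
    "GenerativeModel",
    "ModelConfigError",
    "preference_vector",
    "make_default_model",
    "validate_model",
]

#: tolerance for simplex / column-stochastic checks
ATOL = 1e-9

#: policy indices, fixed across the package
POLICY_UP, POLICY_DOWN, POLICY_STAY = 0, 1, 2
N_POLICIES = 3


class ModelConfigError(ValueError):
    """Raised when a generative-model parameter is invalid."""


class OrderLabel(enum.Enum):
    """The three orders of one agent: Real, Symbolic, Imaginary."""

    REAL = "Real"
    SYMBOLIC = "Symbolic"
    IMAGINARY = "Imaginary"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class GenerativeModel:
    """The (A, B, C, D) structure one unit uses to infer and plan.

    Parameters
    ----------
    n_states
        Cardinality of the discrete state space (also the observation space).
    A
        ``(n_states, n_states)`` likelihood matrix, column-stochastic.
    B
        ``(n_states, n_states, 3)`` transition tensor; each policy slice is
        column-stochastic.
    C
        Length-``n_states`` preference distribution over observations.
    D
        Length-``n_states`` prior belief over hidden states.
    """

    n_states: int
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    meta: dict = field(default_factory=dict)

    def copy(self) -> "GenerativeModel":
        return GenerativeModel(
            n_states=self.n_states,
            A=self.A.copy(),
            B=self.B.copy(),
            C=self.C.copy(),
            D=self.D.copy(),
            meta=dict(self.meta),
        )

    # -- serialization -------------------------------------------------

    def params_dict(self) -> dict:
        """JSON-serializable record of the constructor parameters (if built
        by :func:`make_default_model`)."""
        return dict(self.meta) | {"n_states": self.n_states}

    def matrices_to_csv(self, directory) -> list:
        """Write A, C, D and the three policy slices of B as CSV tables.

        Returns the list of paths written.
        """
        import pathlib

        import pandas as pd

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        written.append(directory / "A.csv")
        pd.DataFrame(self.A).to_csv(written[-1], index=False)
        for pi, name in enumerate(("B_up", "B_down", "B_stay")):
            written.append(directory / f"{name}.csv")
            pd.DataFrame(self.B[:, :, pi]).to_csv(written[-1], index=False)
        written.append(directory / "C.csv")
        pd.DataFrame({"C": self.C}).to_csv(written[-1], index=False)
        written.append(directory / "D.csv")
        pd.DataFrame({"D": self.D}).to_csv(written[-1], index=False)
        return written


def preference_vector(
    target: int, sharpness: float, n_states: int
) -> np.ndarray:
    """Preference distribution concentrated on one observation.

    ``C(o) \\propto exp(sharpness * 1[o == target])``, normalized. Sharpness 0
    gives the uniform distribution; large sharpness approaches a one-hot at
    ``target`` while keeping every entry strictly positive, so KL terms
    against ``C`` stay finite.
    """
    if not 0 <= target < n_states:
        raise IndexError(
            f"preference target {target} out of range [0, {n_states})"
        )
    if sharpness < 0:
        raise ModelConfigError(f"preference_sharpness must be >= 0, got {sharpness}")
    logits = np.zeros(n_states)
    logits[target] = float(sharpness)
    c = np.exp(logits - logits.max())
    return c / c.sum()


def make_default_model(
    n_states: int = 5,
    likelihood_noise: float = 0.2,
    preferred_obs: int | None = None,
    preference_sharpness: float = 4.0,
) -> GenerativeModel:
    """Build the standard unit model: noisy-identity likelihood, deterministic
    clamped move policies, optional sharp preference, uniform prior.

    Parameters
    ----------
    n_states
        State-space size (>= 2). Default 5 (states 0..4).
    likelihood_noise
        Probability mass taken off the diagonal of A; ``A[o,s]`` is
        ``1 - likelihood_noise`` for ``o == s`` and
        ``likelihood_noise / (n_states - 1)`` otherwise.
    preferred_obs
        Index of the preferred observation, or None for a uniform preference.
    preference_sharpness
        Log-odds of the preferred observation against any other one.
    """
    if not (isinstance(n_states, (int, np.integer)) and n_states >= 2):
        raise ModelConfigError(f"n_states must be an integer >= 2, got {n_states}")
    if not 0 <= likelihood_noise < 1:
        raise ModelConfigError(
            f"likelihood_noise must lie in [0, 1), got {likelihood_noise}"
        )
    if preferred_obs is not None and not 0 <= preferred_obs < n_states:
        raise ModelConfigError(
            f"preferred_obs {preferred_obs} out of range [0, {n_states})"
        )

    n = int(n_states)
    off = likelihood_noise / (n - 1)
    A = np.full((n, n), off)
    np.fill_diagonal(A, 1.0 - likelihood_noise)

    B = np.zeros((n, n, N_POLICIES))
    for s in range(n):
        B[min(s + 1, n - 1), s, POLICY_UP] = 1.0
        B[max(s - 1, 0), s, POLICY_DOWN] = 1.0
        B[s, s, POLICY_STAY] = 1.0

    if preferred_obs is None:
        C = np.full(n, 1.0 / n)
    else:
        C = preference_vector(preferred_obs, preference_sharpness, n)
    D = np.full(n, 1.0 / n)

    return GenerativeModel(
        n_states=n,
        A=A,
        B=B,
        C=C,
        D=D,
        meta={
            "likelihood_noise": float(likelihood_noise),
            "preferred_obs": None if preferred_obs is None else int(preferred_obs),
            "preference_sharpness": float(preference_sharpness),
        },
    )


def validate_model(m: GenerativeModel) -> list[str]:
    """Check every structural invariant of a generative model.

    Returns a list of human-readable violation descriptions; the empty list
    means the model is valid. Never raises.
    """
    violations: list[str] = []
    n = m.n_states
    if n < 2:
        violations.append(f"n_states must be >= 2, got {n}")
        return violations

    if m.A.shape != (n, n):
        violations.append(f"A has shape {m.A.shape}, expected {(n, n)}")
    else:
        if np.any(m.A < 0):
            idx = tuple(int(i) for i in np.argwhere(m.A < 0)[0])
            violations.append(f"A has negative entry {m.A[idx]:.6g} at {idx}")
        colsums = m.A.sum(axis=0)
        for s in np.where(~np.isclose(colsums, 1.0, rtol=0, atol=ATOL))[0]:
            violations.append(
                f"A column {int(s)} sums to {colsums[s]:.12g}, expected 1"
            )

    if m.B.shape != (n, n, N_POLICIES):
        violations.append(f"B has shape {m.B.shape}, expected {(n, n, N_POLICIES)}")
    else:
        if np.any(m.B < 0):
            idx = tuple(int(i) for i in np.argwhere(m.B < 0)[0])
            violations.append(f"B has negative entry {m.B[idx]:.6g} at {idx}")
        for pi in range(N_POLICIES):
            colsums = m.B[:, :, pi].sum(axis=0)
            for s in np.where(~np.isclose(colsums, 1.0, rtol=0, atol=ATOL))[0]:
                violations.append(
                    f"B[:,:,{pi}] column {int(s)} sums to {colsums[s]:.12g},"
                    " expected 1"
                )

    for name, vec in (("C", m.C), ("D", m.D)):
        if vec.shape != (n,):
            violations.append(f"{name} has shape {vec.shape}, expected {(n,)}")
            continue
        if np.any(vec < 0):
            i = int(np.argwhere(vec < 0)[0][0])
            violations.append(f"{name} has negative entry {vec[i]:.6g} at index {i}")
        total = vec.sum()
        if not np.isclose(total, 1.0, rtol=0, atol=ATOL):
            violations.append(f"{name} sums to {total:.12g}, expected 1")

    return violations
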
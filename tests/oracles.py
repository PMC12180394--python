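"""Independent brute-force oracles the implementation is checked against.

Everything here is written as plain enumeration of the defining formulas —
Bayes' rule, the evidence lower bound, and the ambiguity/risk sums — with
no code shared with the package's inference path.
"""

import numpy as np

from fep_rsi.generative_model import GenerativeModel


def bayes_posterior(A: np.ndarray, o: int, prior: np.ndarray) -> np.ndarray:
    """P(s|o) = P(o|s) P(s) / P(o) by explicit enumeration."""
    joint = np.array([A[o, s] * prior[s] for s in range(len(prior))])
    return joint / joint.sum()


def negative_elbo(
    A: np.ndarray, o: int, prior: np.ndarray, q: np.ndarray
) -> float:
    """-ELBO = E_q[log q(s)] - E_q[log p(s, o)] by explicit enumeration."""
    total = 0.0
    for s in range(len(q)):
        if q[s] > 0:
            total += q[s] * (np.log(q[s]) - np.log(prior[s] * A[o, s]))
    return total


def efe_enumeration(
    model: GenerativeModel, q: np.ndarray, policy: int
) -> tuple[float, float]:
    """Ambiguity and risk of a policy, term by term over all states/obs."""
    n = model.n_states
    qs = np.array(
        [sum(model.B[s2, s, policy] * q[s] for s in range(n)) for s2 in range(n)]
    )
    ambiguity = 0.0
    for s in range(n):
        h = 0.0
        for o in range(n):
            if model.A[o, s] > 0:
                h -= model.A[o, s] * np.log(model.A[o, s])
        ambiguity += qs[s] * h
    qo = np.array([sum(model.A[o, s] * qs[s] for s in range(n)) for o in range(n)])
    risk = 0.0
    for o in range(n):
        if qo[o] > 0:
            risk += qo[o] * (np.log(qo[o]) - np.log(model.C[o]))
    return ambiguity, risk


def random_model(rng: np.random.Generator, n_states: int) -> GenerativeModel:
    """A random, strictly positive generative model for oracle batteries."""
    n = n_states
    A = rng.dirichlet(np.ones(n), size=n).T  # columns are simplexes
    B = np.stack(
        [rng.dirichlet(np.ones(n), size=n).T for _ in range(3)], axis=2
    )
    return GenerativeModel(
        n_states=n,
        A=A,
        B=B,
        C=rng.dirichlet(np.ones(n)),
        D=rng.dirichlet(np.ones(n)),
    )
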
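import numpy as np
import pytest

import gseqdesign as g


@pytest.fixture(scope="session")
def example_spec() -> g.DesignSpec:
    """Dichotomous equality design: alpha=0.05, beta=0.1, p_T=0.1, p_C=0.2, k=1."""
    return g.DesignSpec(
        outcome_type="dichotomous",
        hypothesis="equality",
        alpha=0.05,
        beta=0.1,
        p_treat=0.1,
        p_control=0.2,
    )


@pytest.fixture(scope="session")
def fixed_example(example_spec) -> g.FixedDesign:
    return g.sample_size(example_spec)


@pytest.fixture(scope="session")
def pocock_plan5(fixed_example) -> g.SequentialPlan:
    return g.solve_plan("pocock", 5, 0.05, 0.1, fixed=fixed_example)


@pytest.fixture(scope="session")
def obf_plan5(fixed_example) -> g.SequentialPlan:
    return g.solve_plan("obf", 5, 0.05, 0.1, fixed=fixed_example)


@pytest.fixture(scope="session")
def wt_plan5(fixed_example) -> g.SequentialPlan:
    return g.solve_plan("wt", 5, 0.05, 0.1, delta_shape=0.25, fixed=fixed_example)


@pytest.fixture(scope="session")
def iw_plan5(fixed_example) -> g.SequentialPlan:
    return g.solve_plan("iw", 5, 0.05, 0.1, delta_shape=0.25, fixed=fixed_example)


def mc_sequential_reject(
    efficacy,
    futility,
    info_fractions,
    drift,
    n_paths,
    seed,
) -> tuple[float, float]:
    """Monte Carlo oracle for boundary-crossing probabilities.

    Simulates the correlated sequential z statistics directly as scaled
    partial sums of independent normal increments and applies the stopping
    rule path by path.  Independent of the recursive-integration engine.
    Returns (total rejection rate, its binomial standard error).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(info_fractions, dtype=float)
    dt = np.diff(np.concatenate([[0.0], t]))
    efficacy = np.asarray(efficacy, dtype=float)
    has_fut = futility is not None and len(futility) > 0
    fut = np.asarray(futility, dtype=float) if has_fut else None
    s = np.zeros(n_paths)
    active = np.ones(n_paths, dtype=bool)
    rejected = np.zeros(n_paths, dtype=bool)
    for r in range(t.size):
        s = s + rng.normal(drift * dt[r], np.sqrt(dt[r]), size=n_paths)
        z = s / np.sqrt(t[r])
        hit = active & (np.abs(z) >= efficacy[r])
        rejected |= hit
        active &= ~hit
        if has_fut:
            active &= ~(np.abs(z) < fut[r])
    rate = rejected.mean()
    se = np.sqrt(max(rate * (1 - rate), 1e-12) / n_paths)
    return float(rate), float(se)
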
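"""Stack-based generator of realistic LCDM-like distance samples.

Real LCDM distances, partitioned into half-millimeter "stacks" away from
the GM/WM surface, have stack frequencies that fall off with distance.
The generator draws a stack index J from a probability vector over stacks,
a uniform offset U on (0, r), and emits the distance d = (J + U) / 2, so
that with the reference probability vector and r = 1 the sample spans
[0, 6.0] mm and reproduces the reference frequency profile exactly
(floor(2 d) recovers the stack).

Two parameters deform the reference:

* ``eta`` (a non-negative integer) shifts stack mass: the stack counts
  nu_i are replaced by |nu_i - eta| sorted in descending order, with the
  removed mass appended as an extra remainder stack at the far end, so
  larger eta moves mass toward larger distances.
* ``r`` in (0, 2) widens the per-stack uniform spread: r > 1 makes
  consecutive stacks overlap, accumulating values near the half-integer
  stack boundaries and perturbing the ranking of distances.

The reference and alternative probability vectors are used as printed at
three decimals and renormalized; the underlying integer voxel counts are
not recoverable from the rounded values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reference stack probabilities (12 stacks, 0..11), printed to 3 decimals.
REFERENCE_PMF = (0.177, 0.163, 0.151, 0.143, 0.126, 0.109,
                 0.070, 0.036, 0.012, 0.007, 0.005, 0.001)

#: Alternative probabilities for sample Z (13 entries; the far tail gains
#: mass relative to the reference, so Z has more large distances).
ALT_Z_PMF = (0.171, 0.158, 0.146, 0.138, 0.121, 0.104,
             0.065, 0.051, 0.031, 0.008, 0.003, 0.003, 0.001)

#: Total voxel count and maximum stack count of the reference region, used
#: only to bound eta in the shift machinery.
REFERENCE_TOTAL = 11659
REFERENCE_MAX_COUNT = 2059

#: Scale divisor turning (stack + offset) into millimeters.
SCALE_DIVISOR = 2.0


@dataclass(frozen=True)
class StackDistribution:
    """A probability vector over distance stacks 0..m."""

    probabilities: np.ndarray
    source: str = "custom"

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or len(p) == 0:
            raise ValueError("probabilities must be a nonempty vector")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"probabilities sum to {total:.4f}, expected ~1")
        object.__setattr__(self, "probabilities", p / total)

    @property
    def n_stacks(self) -> int:
        return len(self.probabilities)

    @property
    def max_stack(self) -> int:
        return len(self.probabilities) - 1


@dataclass(frozen=True)
class SimSampleSpec:
    """Parameters for one simulated sample: pmf, spread r, size n."""

    pmf: StackDistribution
    r: float = 1.0
    n: int = 10000

    def __post_init__(self):
        if not (0 < self.r < 2):
            raise ValueError("r must lie in (0, 2)")
        if self.n < 0:
            raise ValueError("n must be >= 0")

    @property
    def support_upper(self) -> float:
        """Upper bound of the generated distances, (m + r) / scale."""
        return (self.pmf.max_stack + self.r) / SCALE_DIVISOR


@dataclass(frozen=True)
class MCScenario:
    """Named sample specs X, Y, Z for one Monte Carlo scenario."""

    specs: dict  # name -> SimSampleSpec
    tag: str = "custom"

    def __post_init__(self):
        if self.tag in ("null", "alternative") and set(self.specs) != {"X", "Y", "Z"}:
            raise ValueError(f"{self.tag} scenario requires exactly X, Y, Z")


def reference_stack_pmf() -> StackDistribution:
    """The printed 12-entry reference stack probability vector."""
    return StackDistribution(REFERENCE_PMF, source="reference")


def alt_z_pmf() -> StackDistribution:
    """The printed 13-entry alternative vector for sample Z."""
    return StackDistribution(ALT_Z_PMF, source="printed-alternative")


def derive_shifted_pmf(base_counts, eta: int, total: int | None = None) -> StackDistribution:
    """Shift stack mass toward larger distances by the eta machinery.

    Computes |nu_i - eta| for each base count, sorts the results in
    descending order (a stable sort), appends the remainder
    ``total - sum|nu_i - eta|`` as the final stack, and normalizes by
    ``total``.  With eta = 0 and counts summing to ``total`` this returns
    the base proportions with zero remainder mass.
    """
    counts = np.asarray(base_counts, dtype=np.int64)
    if total is None:
        total = int(counts.sum())
    if eta < 0 or eta >= counts.max():
        raise ValueError("eta must satisfy 0 <= eta < max(base_counts)")
    shifted = np.abs(counts - eta)
    shifted = np.sort(shifted, kind="stable")[::-1]
    remainder = total - shifted.sum()
    if remainder < 0:
        raise ValueError("negative remainder mass; eta too large for total")
    probs = np.concatenate([shifted, [remainder]]) / total
    return StackDistribution(probs, source=f"derived(eta={eta})")


def generate_sample(spec: SimSampleSpec, rng) -> np.ndarray:
    """Draw ``spec.n`` distances: d = (J + U) / 2, J ~ pmf, U ~ Unif[0, r).

    ``rng`` is a seed or :class:`numpy.random.Generator`.  The half-open
    offset interval makes floor(2 d) recover the stack index exactly when
    r = 1.
    """
    rng = np.random.default_rng(rng)
    j = rng.choice(spec.pmf.n_stacks, size=spec.n, p=spec.pmf.probabilities)
    u = rng.uniform(0.0, spec.r, size=spec.n)
    return (j + u) / SCALE_DIVISOR


def null_scenario(n: int = 10000) -> MCScenario:
    """X, Y, Z all from the reference pmf with r = 1 (eta = 0)."""
    spec = SimSampleSpec(reference_stack_pmf(), r=1.0, n=n)
    return MCScenario({"X": spec, "Y": spec, "Z": spec}, tag="null")


def alt_scenario(n: int = 10000) -> MCScenario:
    """The alternative: Y widened (r = 1.2), Z from the printed shifted pmf.

    X is as under the null; Y shares the reference pmf but r = 1.2, which
    accumulates values near the half-millimeter stack overlaps; Z keeps
    r = 1 but draws stacks from the printed alternative vector, which puts
    more mass on the far stacks (distances above ~4 mm).
    """
    ref = reference_stack_pmf()
    return MCScenario(
        {
            "X": SimSampleSpec(ref, r=1.0, n=n),
            "Y": SimSampleSpec(ref, r=1.2, n=n),
            "Z": SimSampleSpec(alt_z_pmf(), r=1.0, n=n),
        },
        tag="alternative",
    )


def generate_scenario(scenario: MCScenario, seed) -> dict:
    """One replication of a scenario: sample name -> distance array.

    ``seed`` (an int or :class:`numpy.random.SeedSequence`) is split
    deterministically across the samples, one child stream per sample in
    the order the scenario names them.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(len(scenario.specs))
    return {
        name: generate_sample(spec, np.random.default_rng(child))
        for (name, spec), child in zip(scenario.specs.items(), children)
    }
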
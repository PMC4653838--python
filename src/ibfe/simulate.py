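"""Synthetic multi-omics benchmark scenarios with planted cluster structure.

Five scenarios isolate failure modes of naive multi-view integration.
Each builds one or two noiseless block "prototype" matrices (patients in
a cluster share a block of elevated variables) and derives two observed
data types from them:

* **sd1** — scale conflicts: one noisy prototype D0, observed as the
  elementwise q-th power (T1) and as q raised to each entry (T2).
* **sd2** — noise-type conflicts: the same clean prototype plus
  Normal(0, q) noise (T1) vs Uniform(0, q) noise (T2).
* **sd3** — noise-size conflicts: Normal noise with two different
  standard deviations.
* **sd4** — incomplete patient relationships: each data type defines the
  cluster structure of only half of the patients.
* **sd5** — conflicting patient relationships: the two data types plant
  two different bipartitions whose common refinement is a 4-class truth.

Defaults follow the simplistic study design: 100 patients (two blocks of
50) x 100 variables, block amplitude 1, and, for sd1, standard-normal
noise on every prototype entry.  A "realistic" augmentation doubles the
second class, appends 50 unclassified (pure-noise) patients, and pads
each data type with 10x uninformative standard-normal features.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCENARIOS",
    "SimulationSpec",
    "SimulationOutput",
    "simulate",
    "make_sd1",
    "make_sd2",
    "make_sd3",
    "make_sd4",
    "make_sd5",
    "realistic_augment",
]

SCENARIOS = ("sd1", "sd2", "sd3", "sd4", "sd5")

#: per-scenario default for the control parameter q: sd1's scale exponent is
#: the value used throughout the printed benchmark; the noise scale of the
#: other scenarios is not pinned down anywhere, so a unit scale is used.
DEFAULT_Q = {"sd1": 20.0, "sd2": 1.0, "sd3": 1.0, "sd4": 1.0, "sd5": 1.0}

_N_UNCLASSIFIED = 50  # extra unclassified patients in realistic mode
_NOISE_FEATURE_FACTOR = 10  # uninformative features added per informative one


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated benchmark dataset.

    Parameters
    ----------
    scenario : {"sd1", ..., "sd5"}
    q : float, optional
        Scenario control parameter: the power/exponential base for sd1
        (must be a positive integer value; q=1 degenerates), the noise
        scale for sd2/sd4/sd5.  Defaults per scenario (20 for sd1, 1
        otherwise).  Unused by sd3.
    sigma_pair : (float, float)
        The two normal noise standard deviations of sd3; must differ.
    realistic : bool
        Apply the realistic augmentation (unequal class sizes,
        unclassified patients, noisy feature padding).
    seed : int
        Master seed; output is a deterministic function of the spec.
    n_patients_per_block : int
        Patients per planted class (two classes before augmentation).
    n_informative_vars : int
        Informative variables per data type.
    """

    scenario: str
    q: float | None = None
    sigma_pair: tuple[float, float] = (0.5, 2.0)
    realistic: bool = False
    seed: int = 0
    n_patients_per_block: int = 50
    n_informative_vars: int = 100

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.q is None:
            object.__setattr__(self, "q", DEFAULT_Q[self.scenario])
        if not self.q > 0:
            raise ValueError(f"q must be positive, got {self.q}")
        s1, s2 = self.sigma_pair
        if not (s1 > 0 and s2 > 0):
            raise ValueError(f"sigma_pair entries must be positive, got {self.sigma_pair}")
        if self.scenario == "sd3" and s1 == s2:
            raise ValueError("sd3 requires two different noise standard deviations")
        if self.scenario == "sd1":
            if not float(self.q).is_integer():
                raise ValueError(
                    "sd1 requires an integer q: fractional powers of negative "
                    "noisy prototype entries are undefined"
                )
            if self.q == 1:
                warnings.warn(
                    "sd1 with q=1 is degenerate: the exponential data type "
                    "1**x is constant", UserWarning, stacklevel=3,
                )
        if self.n_patients_per_block < 2 or self.n_informative_vars < 4:
            raise ValueError("need at least 2 patients per block and 4 informative variables")
        if self.scenario == "sd5" and (self.n_patients_per_block * 3) % 5 != 0:
            raise ValueError("sd5 block size must make 0.6*block an integer (e.g. 50)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationOutput:
    """Generated data types plus ground truth for one simulation draw."""

    datasets: list[pd.DataFrame]
    true_labels: pd.Series
    unclassified_mask: pd.Series
    spec: SimulationSpec
    augmented: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def classified(self) -> pd.Index:
        """Ids of patients that carry a ground-truth class label."""
        return self.true_labels.index[~self.unclassified_mask]


def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(n)]


def _frames(arrays, n_feat: int, label_prefix: str = "data"):
    ids = _patient_ids(arrays[0].shape[0])
    cols = [f"v{j + 1}" for j in range(n_feat)]
    return [
        pd.DataFrame(a, index=ids, columns=cols)
        for a in arrays
    ]


def _sd1_prototype(b: int, n: int) -> np.ndarray:
    """Two complementary blocks: class 1 high on the first half of the
    variables, class 2 on the second half."""
    proto = np.zeros((2 * b, n))
    h = n // 2
    proto[:b, :h] = 1.0
    proto[b:, h:] = 1.0
    return proto


def _two_class_labels(b: int) -> np.ndarray:
    return np.repeat([1, 2], b)


def _scenario_prototypes(spec: SimulationSpec) -> tuple[list[np.ndarray], np.ndarray]:
    """Noiseless prototype matrices and the true labels for a scenario."""
    b, n = spec.n_patients_per_block, spec.n_informative_vars
    h = n // 2
    if spec.scenario in ("sd1", "sd2", "sd3"):
        return [_sd1_prototype(b, n)], _two_class_labels(b)
    if spec.scenario == "sd4":
        d1 = np.zeros((2 * b, n))
        d1[:b, :h] = 1.0  # only the first class is defined here
        d2 = np.zeros((2 * b, n))
        d2[b:, h:] = 1.0  # only the second class is defined here
        return [d1, d2], _two_class_labels(b)
    # sd5: first data type plants the standard bipartition; the second
    # plants an offset bipartition (outer 60% vs middle 40%), mirroring the
    # same block style so both carry equal signal strength.  The 4-class
    # truth is the common refinement of the two bipartitions.
    d1 = _sd1_prototype(b, n)
    edge = (3 * b) // 5  # 30 for b=50
    m = 2 * b
    outer = np.zeros(m, dtype=bool)
    outer[:edge] = True
    outer[m - edge:] = True
    d2 = np.zeros((m, n))
    d2[outer, :h] = 1.0
    d2[~outer, h:] = 1.0
    labels = np.empty(m, dtype=int)
    labels[:edge] = 1
    labels[edge:b] = 2
    labels[b:m - edge] = 3
    labels[m - edge:] = 4
    return [d1, d2], labels


def _generate(spec: SimulationSpec) -> SimulationOutput:
    b, n, q = spec.n_patients_per_block, spec.n_informative_vars, float(spec.q)
    protos, labels = _scenario_prototypes(spec)
    if spec.realistic:
        # double the second class (fresh prototype rows; noise is drawn below)
        # and append unclassified patients whose prototype rows are all zero
        second = labels == 2
        protos = [
            np.vstack([p, p[second], np.zeros((_N_UNCLASSIFIED, p.shape[1]))])
            for p in protos
        ]
        labels = np.concatenate(
            [labels, labels[second], np.zeros(_N_UNCLASSIFIED, dtype=int)]
        )
    m = protos[0].shape[0]

    # independent child streams per noise source so each data type's noise is
    # independent and the simplistic/realistic paths draw fresh noise
    ss = np.random.SeedSequence([spec.seed, int(spec.realistic)])
    rng_d0, rng_t1, rng_t2, rng_pad = [np.random.default_rng(c) for c in ss.spawn(4)]

    if spec.scenario == "sd1":
        d0 = protos[0] + rng_d0.standard_normal((m, n))
        t1 = d0 ** q
        t2 = q ** d0
        extras = {"d0": d0}
    elif spec.scenario == "sd2":
        t1 = protos[0] + rng_t1.normal(0.0, q, size=(m, n))
        t2 = protos[0] + rng_t2.uniform(0.0, q, size=(m, n))
        extras = {"d0": protos[0]}
    elif spec.scenario == "sd3":
        s1, s2 = spec.sigma_pair
        t1 = protos[0] + rng_t1.normal(0.0, s1, size=(m, n))
        t2 = protos[0] + rng_t2.normal(0.0, s2, size=(m, n))
        extras = {"d0": protos[0]}
    else:  # sd4, sd5: one prototype per data type, shared noise scale q
        t1 = protos[0] + rng_t1.normal(0.0, q, size=(m, n))
        t2 = protos[1] + rng_t2.normal(0.0, q, size=(m, n))
        extras = {"d0_1": protos[0], "d0_2": protos[1]}

    arrays = [t1, t2]
    n_total = n
    if spec.realistic:
        n_pad = _NOISE_FEATURE_FACTOR * n
        arrays = [
            np.hstack([a, rng_pad.standard_normal((m, n_pad))]) for a in arrays
        ]
        n_total = n + n_pad

    datasets = _frames(arrays, n_total)
    ids = datasets[0].index
    true_labels = pd.Series(labels, index=ids, name="cluster")
    unclassified = pd.Series(labels == 0, index=ids, name="unclassified")
    return SimulationOutput(
        datasets=datasets,
        true_labels=true_labels,
        unclassified_mask=unclassified,
        spec=spec,
        augmented=spec.realistic,
        extras=extras,
    )


def simulate(spec: SimulationSpec | None = None, **kwargs) -> SimulationOutput:
    """Generate one simulation draw, from a spec or keyword arguments."""
    if spec is None:
        spec = SimulationSpec(**kwargs)
    elif kwargs:
        spec = dataclasses.replace(spec, **kwargs)
    return _generate(spec)


def _scenario_maker(name):
    def maker(spec: SimulationSpec) -> SimulationOutput:
        if spec.scenario != name:
            raise ValueError(f"spec.scenario is {spec.scenario!r}, expected {name!r}")
        return _generate(spec)

    maker.__name__ = f"make_{name}"
    maker.__doc__ = f"Generate one draw of scenario {name} from its spec."
    return maker


make_sd1 = _scenario_maker("sd1")
make_sd2 = _scenario_maker("sd2")
make_sd3 = _scenario_maker("sd3")
make_sd4 = _scenario_maker("sd4")
make_sd5 = _scenario_maker("sd5")


def realistic_augment(base: SimulationOutput) -> SimulationOutput:
    """Realistic version of a simplistic draw (fresh noise, same spec seed).

    The augmentation regenerates the scenario with the second class
    doubled, 50 unclassified pure-noise patients appended and a 10x pad of
    uninformative standard-normal features per data type.  All noise is
    freshly drawn (deterministically from the spec seed); the informative
    columns are a regenerated prototype + noise, not copies of the base
    draw.  Applying it to an already augmented output is an error.
    """
    if base.augmented:
        raise ValueError("output is already augmented")
    return _generate(dataclasses.replace(base.spec, realistic=True))
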
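"""Synthetic study generator.

Produces every input the analysis stages consume — a phylogeny, evolved
plumage states, specimen score tables, patch-color and morphometric tables,
and species-level socioecological covariates — with the statistical
structure the downstream methods assume: bimodal vs unimodal ordinal score
distributions with a controllable male-like ("androchrome") fraction,
3-state Markov tip data on simulated trees, two-cluster patch-color data
with a heterochrome-to-androchrome continuum and an optional planted
bill-length slope, and Brownian-structured covariates with planted
associations to female-limited polymorphism (FLP).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import mk, trees
from .errors import InvalidArgumentError

__all__ = [
    "SimulationSpec",
    "simulate_yule_tree",
    "simulate_mk_tips",
    "simulate_specimen_scores",
    "simulate_color_morphometrics",
    "simulate_covariates",
]

# re-exported: the tree generator lives with the other tree utilities
simulate_yule_tree = trees.simulate_yule_tree


@dataclass
class SimulationSpec:
    """Knobs for the synthetic study.

    Defaults emulate the sampling structure of a large museum-skin survey:
    ~200 classifiable species, 19 female and 10 male skins per species for
    scoring, photographic panels of 10 androchrome males, 6 Class-1 females
    and 11 variable females per species with 17 color patches, and plumage
    states evolving under an equal-rates Markov model at rate 0.9.
    """

    n_species: int = 200
    birth_rate: float = 1.0
    #: rescale the simulated tree to this mean root-to-tip depth (None keeps
    #: raw Yule depths); unit depth puts the rate-0.9 default in the
    #: weak-saturation regime where ancestral states are informative
    tree_depth: float | None = 1.0
    #: 3x3 rate matrix used to evolve plumage states (None -> ER, rate 0.9)
    q_true: np.ndarray | None = None
    n_females: int = 19
    n_males: int = 10
    #: fraction of females drawn from the androchrome component in FLP species
    androchrome_freq: float = 0.3
    #: probability a specimen's ordinal class is misread by +-1
    class_noise: float = 0.0
    n_patches: int = 17
    #: male-female mean distance in channel units along the color axis
    color_separation: float = 80.0
    #: isotropic per-channel color noise (sd, channel units)
    color_noise: float = 5.0
    #: planted change in bill length (mm) per unit of the androchromy axis
    planted_slope: float = 0.0
    #: residual sd of bill length (mm)
    bill_noise: float = 0.5
    #: photographic panel sizes per species
    n_class1_females: int = 6
    n_variable_females: int = 11
    #: covariate -> effect size on the latent FLP predictor (probit scale)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "n_females", "n_males", "n_patches",
                     "n_class1_females", "n_variable_females"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not 0.0 <= self.androchrome_freq <= 1.0:
            raise InvalidArgumentError("androchrome_freq must be in [0, 1]")
        if not 0.0 <= self.class_noise < 0.5:
            raise InvalidArgumentError("class_noise must be in [0, 0.5)")
        if self.birth_rate <= 0:
            raise InvalidArgumentError("birth_rate must be > 0")

    def simulate_tree(self, seed: int | None = None) -> dendropy.Tree:
        """Yule tree at the spec's size, rescaled to ``tree_depth``."""
        tree = trees.simulate_yule_tree(self.n_species, self.birth_rate,
                                        self.seed if seed is None else seed)
        if self.tree_depth is not None:
            trees.scale_to_depth(tree, self.tree_depth)
        return tree

    @property
    def q_matrix(self) -> np.ndarray:
        if self.q_true is not None:
            return np.asarray(self.q_true, dtype=float)
        return mk.build_rate_matrix("ER", [0.9]).matrix


def _rng(seed, *salt) -> np.random.Generator:
    return np.random.default_rng([int(seed), *salt])


def simulate_mk_tips(tree: dendropy.Tree, q_matrix, root_prior,
                     seed: int) -> tuple[dict[str, str], dict[str, str]]:
    """Evolve a 3-state character along the tree.

    Draws the root state from ``root_prior``, then transitions along each
    branch with probability matrix ``expm(Q t)``.

    Returns
    -------
    (tip_states, node_states)
        Maps from tip label -> state name and from every node label
        (tips and internal) -> state name.
    """
    Q = np.asarray(q_matrix, dtype=float)
    mk.validate_q(Q)
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (3,) or abs(prior.sum() - 1.0) > 1e-8 or (prior < 0).any():
        raise InvalidArgumentError("root_prior must be a 3-vector summing to 1")
    rng = _rng(seed, 0x_3A7E)
    node_state: dict[dendropy.Node, int] = {}
    tip_states: dict[str, str] = {}
    all_states: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            s = int(rng.choice(3, p=prior))
        else:
            t = nd.edge.length or 0.0
            P = mk.transition_probabilities(Q, t)
            s = int(rng.choice(3, p=P[node_state[nd.parent_node]]))
        node_state[nd] = s
        label = nd.taxon.label if nd.is_leaf() else nd.label
        all_states[label] = mk.STATES[s]
        if nd.is_leaf():
            tip_states[label] = mk.STATES[s]
    return tip_states, all_states

# ordinal class mixture components: discrete morphs, so heterochrome
# females concentrate in Class 1 and androchrome females in Class 4
_HET_P = {1: 0.9, 2: 0.1}
_AND_P = {3: 0.1, 4: 0.9}


def _perturb_classes(classes: np.ndarray, noise: float,
                     rng: np.random.Generator) -> np.ndarray:
    if noise <= 0:
        return classes
    flip = rng.random(classes.size) < noise
    step = rng.choice([-1, 1], size=classes.size)
    return np.clip(classes + flip * step, 1, 4)


def simulate_specimen_scores(spec: SimulationSpec, seed: int | None = None,
                             species: Sequence[str] | None = None,
                             freq_by_species: Mapping[str, float] | None = None,
                             ) -> pd.DataFrame:
    """Specimen table of ordinal plumage scores.

    Females are drawn from a two-component class mixture: a heterochrome
    component over Classes {1, 2} and, with weight ``androchrome_freq``
    (overridable per species), an androchrome component over {3, 4}.  Males
    are all Class 4.  ``class_noise`` then misreads classes by +-1 within
    {1..4}.  Sexing-method tags are drawn with the archive's composition
    (38% gonad, 60% unknown, 2% plumage-sexed).

    Returns a DataFrame with columns species, sex, plumage_class,
    sexing_method.
    """
    seed = spec.seed if seed is None else seed
    rng = _rng(seed, 0x_5C0E)
    if species is None:
        species = [f"sp{i + 1}" for i in range(spec.n_species)]
    rows = []
    for sp in species:
        freq = spec.androchrome_freq
        if freq_by_species is not None:
            freq = freq_by_species.get(sp, freq)
        is_andro = rng.random(spec.n_females) < freq
        classes = np.where(
            is_andro,
            rng.choice(list(_AND_P), spec.n_females, p=list(_AND_P.values())),
            rng.choice(list(_HET_P), spec.n_females, p=list(_HET_P.values())),
        )
        classes = _perturb_classes(classes, spec.class_noise, rng)
        male_classes = _perturb_classes(
            np.full(spec.n_males, 4), spec.class_noise, rng)
        for sex, cls in (("female", classes), ("male", male_classes)):
            methods = rng.choice(["gonad", "unknown", "plumage"], cls.size,
                                 p=[0.38, 0.60, 0.02])
            for c, meth in zip(cls, methods):
                rows.append((sp, sex, int(c), meth))
    return pd.DataFrame(rows, columns=["species", "sex", "plumage_class",
                                       "sexing_method"])


def simulate_color_morphometrics(spec: SimulationSpec, seed: int | None = None,
                                 species: Sequence[str] | None = None,
                                 slope_by_species: Mapping[str, float] | None = None,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patch-color panel and morphometrics for the discriminant analysis.

    For each species, androchrome males and Class-1 females form two
    clusters in the 3*n_patches-dimensional channel space, separated by
    ``color_separation`` along a random unit axis with isotropic noise;
    variable females are placed uniformly along the inter-cluster segment.
    On the latent androchromy coordinate ``a`` (-1 at the Class-1 female
    mean, +1 at the male mean) bill length is
    ``species mean + planted_slope * a + noise``; channel values are
    clamped to [0, 255].

    Returns
    -------
    (color_df, morpho_df)
        color_df: specimen, species, sex, plumage_class, patchNN_R/G/B.
        morpho_df: specimen, species, sex, bill_mm, wing_mm.
    """
    seed = spec.seed if seed is None else seed
    rng = _rng(seed, 0x_C010)
    if species is None:
        species = [f"sp{i + 1}" for i in range(spec.n_species)]
    p = 3 * spec.n_patches
    patch_cols = [f"patch{i + 1:02d}_{ch}" for i in range(spec.n_patches)
                  for ch in "RGB"]
    color_rows, morpho_rows = [], []
    for sp in species:
        slope = spec.planted_slope
        if slope_by_species is not None:
            slope = slope_by_species.get(sp, slope)
        mid = rng.uniform(60.0, 180.0, p)
        axis = rng.normal(size=p)
        axis /= np.linalg.norm(axis)
        bill_mean = rng.uniform(15.0, 35.0)
        wing_mean = rng.uniform(45.0, 75.0)
        groups = (
            [("male", 4, np.full(spec.n_males, 1.0))]
            + [("female", 1, np.full(spec.n_class1_females, -1.0))]
            + [("female", None, rng.uniform(-1.0, 1.0,
                                            spec.n_variable_females))]
        )
        i = 0
        for sex, cls, avals in groups:
            for a in avals:
                i += 1
                sid = f"{sp}_x{i:03d}"
                color = (mid + a * 0.5 * spec.color_separation * axis
                         + rng.normal(0.0, spec.color_noise, p))
                color = np.clip(color, 0.0, 255.0)
                if cls is None:
                    klass = 2 if a < -1 / 3 else (3 if a < 1 / 3 else 4)
                else:
                    klass = cls
                color_rows.append([sid, sp, sex, klass, *color])
                bill = (bill_mean + slope * a
                        + rng.normal(0.0, spec.bill_noise))
                wing = wing_mean + rng.normal(0.0, 2.0)
                morpho_rows.append([sid, sp, sex, bill, wing])
    color_df = pd.DataFrame(
        color_rows, columns=["specimen", "species", "sex", "plumage_class",
                             *patch_cols])
    morpho_df = pd.DataFrame(
        morpho_rows, columns=["specimen", "species", "sex", "bill_mm",
                              "wing_mm"])
    return color_df, morpho_df


#: fraction of non-FLP species that are sexually monochromic
MONOCHROMIC_FRACTION = 0.57
#: marginal prevalence targets for generated binary covariates
MIGRATORY_PREVALENCE = 0.25
DOMINANCE_PREVALENCE = 0.30
FLP_PREVALENCE = 0.25


def simulate_covariates(tree: dendropy.Tree,
                        flp_states: Mapping[str, str] | None = None,
                        effects: Mapping[str, float] | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Species-level socioecological covariates with Brownian structure.

    Continuous covariates evolve by Brownian motion on the tree; binary
    ones threshold a latent Brownian value at the quantile giving the
    target prevalence.  The FLP state is tied to the covariates through a
    latent linear predictor (probit-style): when ``flp_states`` is None,
    FLP is generated as ``eta > threshold`` where ``eta`` sums the supplied
    effect sizes times standardized covariates plus a Brownian residual;
    when plumage states are supplied (e.g. evolved with
    :func:`simulate_mk_tips`), the covariates are instead shifted by
    ``effect * flp`` in standardized units, planting the same association
    conditionally.

    Body length is confined to [6, 22] cm.
    """
    labels = trees.tip_labels(tree)
    if flp_states is not None:
        missing = sorted(set(labels) - set(flp_states))
        if missing:
            raise InvalidArgumentError(f"flp_states missing tips: {missing}")
    effects = dict(effects or {})
    rng = _rng(seed, 0x_C0F)

    def bm(i: int) -> np.ndarray:
        vals = trees.simulate_brownian(tree, 1.0, _rng(seed, 0x_C0F, i))
        z = np.array([vals[lb] for lb in labels])
        sd = z.std()
        return z / sd if sd > 0 else z

    cont = {
        "body_length": np.clip(14.0 + 3.0 * bm(1), 6.0, 22.0),
        "mean_temperature": 20.0 + 5.0 * bm(2),
        "mean_precipitation": np.clip(1500.0 + 600.0 * bm(3), 0.0, None),
        "temperature_predictability": np.clip(0.5 + 0.15 * bm(4), 0.0, 1.0),
        "precipitation_predictability": np.clip(0.5 + 0.15 * bm(5), 0.0, 1.0),
    }
    latents = {"migratory": bm(6), "dominance": bm(7)}
    prevalence = {"migratory": MIGRATORY_PREVALENCE,
                  "dominance": DOMINANCE_PREVALENCE}

    if flp_states is not None and effects:
        # conditional planting: shift each covariate by effect * flp
        flp0 = np.array([int(flp_states[lb] == "FLP") for lb in labels])
        centered = flp0 - flp0.mean()
        for name, eff in effects.items():
            if name in latents:
                latents[name] = latents[name] + eff * centered
            else:
                cont[name] = cont[name] + eff * cont[name].std() * centered
        cont["body_length"] = np.clip(cont["body_length"], 6.0, 22.0)

    binary = {}
    for name, lat in latents.items():
        thresh = np.quantile(lat, 1.0 - prevalence[name])
        binary[name] = (lat > thresh).astype(int)

    def standardized(name: str) -> np.ndarray:
        # observed covariates (binary as 0/1) enter the linear predictor
        x = (binary[name] if name in binary else cont[name]).astype(float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    if flp_states is None:
        eta = bm(8).copy()
        for name, eff in effects.items():
            eta = eta + eff * standardized(name)
        thresh = np.quantile(eta, 1.0 - FLP_PREVALENCE)
        flp = (eta > thresh).astype(int)
    else:
        flp = np.array([int(flp_states[lb] == "FLP") for lb in labels])

    if flp_states is None:
        mono = (rng.random(len(labels)) < MONOCHROMIC_FRACTION) & (flp == 0)
        chromatism = np.where(flp == 1, "FLP",
                              np.where(mono, "monochromic", "dichromic"))
    else:
        chromatism = np.array([flp_states[lb] for lb in labels])

    return pd.DataFrame({
        "species": labels,
        "flp": flp,
        "chromatism": chromatism,
        "migratory": binary["migratory"],
        "dominance": binary["dominance"],
        **cont,
    })
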
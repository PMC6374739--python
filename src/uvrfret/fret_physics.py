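"""Closed-form Förster-transfer forward model for dimer/monomer FRET imaging.

This module is the pure model layer of the package.  It predicts, from first
principles, what a confocal microscope should see when a photoreceptor that
cycles between a homodimer and a monomer is tagged with a GFP/mCherry FRET
pair in one of two labelling schemes:

* ``NcCg`` — a single fusion protein carrying the acceptor (mCherry) at the
  N-terminus and the donor (GFP) at the C-terminus.  A donor in a dimer can
  transfer both *intramolecularly* (to the acceptor on its own polypeptide)
  and *across the dimer interface*; a monomer retains only the intramolecular
  path.
* ``2in1`` — co-expression of a donor-only homotag (GFP-X-GFP) and an
  acceptor-only homotag (mCherry-X-mCherry) at a 1:1 ratio.  Monomers carry a
  single fluorophore species and cannot FRET; random assortment of monomers
  into dimers produces donor/donor, donor/acceptor and acceptor/acceptor
  dimers, of which only the mixed dimer transfers.

From a :class:`PopulationState` (construct, genotype, UV exposure, dimer
fraction) and :class:`FretParams` (transfer efficiencies, bleed-through and
direct-excitation artifact coefficients, detector gains) the module derives a
:class:`SpeciesMix` and, from it, expected channel intensities for the three
standard acquisitions (donor emission at 488 nm excitation, acceptor emission
at 488 nm = FRET channel, acceptor emission at 552 nm) and the expected donor
dequenching after acceptor photobleaching.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SaturationError",
    "FretParams",
    "PopulationState",
    "Species",
    "SpeciesMix",
    "forster_efficiency",
    "combine_acceptors",
    "assort_2in1_dimers",
    "species_mixture",
    "control_mixture",
    "expected_channel_intensities",
    "expected_sensitized_ratio",
    "post_bleach_efficiency",
    "mean_post_bleach_efficiency",
    "expected_bleach_increase",
    "perturb_dimer_fraction",
    "default_dimer_fraction",
    "CONSTRUCTS",
    "GENOTYPES",
    "DEFAULT_DIMER_FRACTION",
]


class SaturationError(ValueError):
    """Raised when transfer is saturated (efficiency 1) and recovery diverges."""


CONSTRUCTS = ("NcCg", "2in1")
GENOTYPES = ("WT", "constitutive_monomer", "constitutive_dimer")

# Dimer fractions defining the study conditions.  The wild type sits in a
# photo-equilibrium: mostly dimeric in the absence of UV-B, partially
# monomerized (with ongoing re-dimerization) after UV-B.  The constitutive
# mutants ignore UV-B; the constitutive monomer keeps a small residual dimer
# fraction modelling weak transient monomer-monomer contacts.
DEFAULT_DIMER_FRACTION: dict[tuple[str, bool], float] = {
    ("WT", False): 0.90,
    ("WT", True): 0.25,
    ("constitutive_dimer", False): 0.95,
    ("constitutive_dimer", True): 0.95,
    ("constitutive_monomer", False): 0.05,
    ("constitutive_monomer", True): 0.05,
}

# Upper bound on the "small residual" dimer fraction allowed for the
# constitutive monomer.
MONOMER_RESIDUAL_MAX = 0.25


def default_dimer_fraction(genotype: str, uv: bool) -> float:
    """Default dimer fraction for a genotype under the given UV-B state."""
    try:
        return DEFAULT_DIMER_FRACTION[(genotype, bool(uv))]
    except KeyError:
        raise ValueError(f"unknown genotype {genotype!r}") from None


# ---------------------------------------------------------------------------
# Elementary transfer laws
# ---------------------------------------------------------------------------

def forster_efficiency(r, R0):
    """Förster transfer efficiency ``R0**6 / (R0**6 + r**6)``.

    Parameters
    ----------
    r : float or array
        Donor-acceptor distance (nm), strictly positive.
    R0 : float
        Förster radius (nm) of the pair, strictly positive.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("distance r must be > 0")
    if not R0 > 0:
        raise ValueError("Förster radius R0 must be > 0")
    out = 1.0 / (1.0 + (r_arr / R0) ** 6)
    return out if out.ndim else float(out)


def combine_acceptors(e_list: Sequence[float], rule: str = "rate") -> float:
    """Combined per-donor efficiency when one donor faces several acceptors.

    The default ``"rate"`` rule treats each acceptor as an independent
    depopulation pathway competing with radiative decay: path *i* with
    single-acceptor efficiency ``e_i`` contributes transfer rate (odds)
    ``o_i = e_i/(1-e_i)`` relative to the unit decay rate, and the combined
    efficiency is ``sum(o)/(1+sum(o))``.  The ``"or"`` rule
    (``1 - prod(1-e_i)``) is provided for sensitivity analysis only.
    """
    es = [float(e) for e in e_list]
    for e in es:
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"efficiency {e} outside [0, 1]")
    if not es:
        return 0.0
    if any(e == 1.0 for e in es):
        return 1.0  # saturated transfer
    if rule == "rate":
        odds = sum(e / (1.0 - e) for e in es)
        return odds / (1.0 + odds)
    if rule == "or":
        prod = math.prod(1.0 - e for e in es)
        return 1.0 - prod
    raise ValueError(f"unknown combination rule {rule!r}")


def assort_2in1_dimers(p_gfp: float) -> dict[str, float]:
    """Random assortment of 1:1 co-expressed homotagged monomers into dimers.

    With probability ``p_gfp`` that a monomer carries the donor homotag, the
    dimer species follow the binomial expansion:
    GG = p^2, GM = 2 p (1-p), MM = (1-p)^2.
    """
    p = float(p_gfp)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_gfp must be within [0, 1]")
    return {"GG": p * p, "GM": 2.0 * p * (1.0 - p), "MM": (1.0 - p) ** 2}


# ---------------------------------------------------------------------------
# Parameter and population containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretParams:
    """Photophysical parameters of the donor/acceptor pair and the detection.

    ``E_intra``/``E_inter`` may be given directly, or derived from effective
    distances ``r_intra``/``r_inter`` and the Förster radius ``R0`` (in which
    case the distance wins and the efficiency field is overwritten).

    ``beta_bleed`` is the fraction of donor emission collected in the acceptor
    band under donor excitation (spectral bleed-through, a false-positive
    source); ``alpha_direct`` is the fraction of full acceptor excitation
    achieved by the donor laser line (direct excitation, the other classic
    false positive).  ``g_donor``/``g_acceptor`` are detector gain/brightness
    scale factors in intensity units per fluorophore.
    """

    R0: float = 5.0
    r_intra: float | None = None
    r_inter: float | None = None
    E_intra: float = 0.15
    E_inter: float = 0.30
    beta_bleed: float = 0.05
    alpha_direct: float = 0.02
    g_donor: float = 1.0
    g_acceptor: float = 1.0
    combine_rule: str = "rate"

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValueError("R0 must be > 0")
        if self.r_intra is not None:
            object.__setattr__(
                self, "E_intra", forster_efficiency(self.r_intra, self.R0)
            )
        if self.r_inter is not None:
            object.__setattr__(
                self, "E_inter", forster_efficiency(self.r_inter, self.R0)
            )
        for name in ("E_intra", "E_inter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("beta_bleed", "alpha_direct"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")
        for name in ("g_donor", "g_acceptor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.combine_rule not in ("rate", "or"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")


@dataclass(frozen=True)
class PopulationState:
    """Molecular ground truth of one experimental condition.

    ``dimer_fraction`` is the fraction of tagged molecules residing in dimers;
    ``None`` selects the genotype/UV default from
    :data:`DEFAULT_DIMER_FRACTION`.  ``p_gfp`` only matters for the ``2in1``
    scheme (probability a molecule carries the donor homotag; the vector
    enforces 1:1 expression, hence the 0.5 default).
    """

    construct: str = "NcCg"
    genotype: str = "WT"
    uv: bool = False
    dimer_fraction: float | None = None
    p_gfp: float = 0.5

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(
                f"unknown construct {self.construct!r}; expected one of {CONSTRUCTS}"
            )
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        if not 0.0 <= self.p_gfp <= 1.0:
            raise ValueError("p_gfp must be within [0, 1]")
        df = self.resolved_dimer_fraction
        if not 0.0 <= df <= 1.0:
            raise ValueError("dimer_fraction must be within [0, 1]")
        if self.genotype == "constitutive_monomer" and df > MONOMER_RESIDUAL_MAX:
            raise ValueError(
                "constitutive_monomer dimer_fraction must stay a small residual "
                f"(<= {MONOMER_RESIDUAL_MAX})"
            )

    @property
    def resolved_dimer_fraction(self) -> float:
        if self.dimer_fraction is not None:
            return float(self.dimer_fraction)
        return default_dimer_fraction(self.genotype, self.uv)


@dataclass(frozen=True)
class Species:
    """One FRET species: a dimer or monomer assembly with its fluorophores.

    ``weight`` is the fraction of assemblies (a dimer counts as one assembly
    of two molecules).  ``paths`` lists the per-donor single-acceptor transfer
    efficiencies; ``efficiency`` is their combined per-donor value.
    """

    label: str
    weight: float
    n_donors: int
    n_acceptors: int
    n_molecules: int
    paths: tuple[float, ...]
    efficiency: float


@dataclass(frozen=True)
class SpeciesMix:
    """A population decomposed into FRET species with assembly weights."""

    species: tuple[Species, ...]
    combine_rule: str = "rate"

    def __post_init__(self) -> None:
        total = sum(s.weight for s in self.species)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"species weights sum to {total}, expected 1")
        for s in self.species:
            if not 0.0 <= s.efficiency <= 1.0:
                raise ValueError(f"species {s.label} efficiency outside [0, 1]")

    @property
    def weights(self) -> dict[str, float]:
        return {s.label: s.weight for s in self.species}

    @property
    def donors_per_molecule(self) -> float:
        mols = sum(s.weight * s.n_molecules for s in self.species)
        return sum(s.weight * s.n_donors for s in self.species) / mols

    @property
    def acceptors_per_molecule(self) -> float:
        mols = sum(s.weight * s.n_molecules for s in self.species)
        return sum(s.weight * s.n_acceptors for s in self.species) / mols

    @property
    def mean_efficiency(self) -> float:
        """Donor-weighted mean transfer efficiency (equal donor brightness)."""
        d_tot = sum(s.weight * s.n_donors for s in self.species)
        if d_tot == 0:
            return 0.0
        return sum(s.weight * s.n_donors * s.efficiency for s in self.species) / d_tot


def _species(label, weight, n_donors, n_acceptors, n_molecules, paths, rule):
    return Species(
        label=label,
        weight=weight,
        n_donors=n_donors,
        n_acceptors=n_acceptors,
        n_molecules=n_molecules,
        paths=tuple(float(p) for p in paths),
        efficiency=combine_acceptors(paths, rule=rule),
    )


def species_mixture(state: PopulationState, params: FretParams) -> SpeciesMix:
    """Decompose a population into FRET species under the labelling scheme.

    NcCg: dimer donors transfer through both the intramolecular path
    (``E_intra``) and one cross-monomer path (``E_inter``); monomer donors
    keep only the intramolecular path.  2in1: the dimer fraction is split by
    random assortment, only mixed (GM) dimers transfer (per-donor ``E_inter``),
    all monomers and same-tag dimers are FRET-silent.
    """
    df = state.resolved_dimer_fraction
    rule = params.combine_rule
    # Assemblies per molecule: a dimer binds two molecules.
    n_dimer = df / 2.0
    n_mono = 1.0 - df
    total = n_dimer + n_mono
    species: list[Species] = []
    if state.construct == "NcCg":
        if n_dimer > 0:
            species.append(_species(
                "NcCg_dimer", n_dimer / total, 2, 2, 2,
                (params.E_intra, params.E_inter), rule))
        if n_mono > 0:
            species.append(_species(
                "NcCg_monomer", n_mono / total, 1, 1, 1,
                (params.E_intra,), rule))
    else:  # 2in1
        assort = assort_2in1_dimers(state.p_gfp)
        p = state.p_gfp
        pieces = [
            ("GG_dimer", n_dimer * assort["GG"], 4, 0, 2, ()),
            ("GM_dimer", n_dimer * assort["GM"], 2, 2, 2, (params.E_inter,)),
            ("MM_dimer", n_dimer * assort["MM"], 0, 4, 2, ()),
            ("G_monomer", n_mono * p, 2, 0, 1, ()),
            ("M_monomer", n_mono * (1.0 - p), 0, 2, 1, ()),
        ]
        for label, w, nd, na, nm, paths in pieces:
            if w > 0:
                species.append(_species(label, w / total, nd, na, nm, paths, rule))
    return SpeciesMix(species=tuple(species), combine_rule=rule)


def control_mixture(kind: str) -> SpeciesMix:
    """Single-tag negative-control population (no FRET possible).

    ``"donor_only"`` carries only GFP, ``"acceptor_only"`` only mCherry —
    the controls used to expose bleed-through/direct-excitation artifacts.
    """
    if kind == "donor_only":
        sp = _species("donor_only", 1.0, 1, 0, 1, (), "rate")
    elif kind == "acceptor_only":
        sp = _species("acceptor_only", 1.0, 0, 1, 1, (), "rate")
    else:
        raise ValueError(f"unknown control kind {kind!r}")
    return SpeciesMix(species=(sp,))


# ---------------------------------------------------------------------------
# Measurement model
# ---------------------------------------------------------------------------

def expected_channel_intensities(mix: SpeciesMix, params: FretParams, donor_density):
    """Expected intensities of the three channels at a given molecule density.

    ``donor_density`` is the tagged-molecule density (molecules per pixel;
    scalar or array).  Returns ``(I_donor_488, I_fret_488, I_acceptor_552)``.

    The donor channel reports the *quenched* donor: what is measured under
    donor excitation is the post-FRET donor signal, proportional to
    ``1 - E``.  The FRET channel stacks sensitized emission on top of two
    artifacts: donor bleed-through into the acceptor band (``beta_bleed`` of
    the donor signal) and direct acceptor excitation by the donor laser
    (``alpha_direct`` of the full acceptor signal).
    """
    n = np.asarray(donor_density, dtype=float)
    if np.any(n < 0):
        raise ValueError("donor_density must be >= 0")
    d = mix.donors_per_molecule
    a = mix.acceptors_per_molecule
    e = mix.mean_efficiency
    i_donor = params.g_donor * n * d * (1.0 - e)
    i_acceptor = params.g_acceptor * n * a
    i_fret = (
        params.g_acceptor * n * d * e
        + params.beta_bleed * i_donor
        + params.alpha_direct * i_acceptor
    )
    if np.ndim(donor_density) == 0:
        return float(i_donor), float(i_fret), float(i_acceptor)
    return i_donor, i_fret, i_acceptor


def expected_sensitized_ratio(mix: SpeciesMix, params: FretParams) -> float:
    """Closed-form expected FRET-channel / donor-channel intensity ratio.

    The density cancels, so this is the noise-free value the sensitized
    emission estimator converges to.
    """
    i_d, i_f, _ = expected_channel_intensities(mix, params, 1.0)
    if i_d <= 0:
        raise ZeroDivisionError("donor channel expectation is zero")
    return i_f / i_d


def post_bleach_efficiency(paths: Sequence[float], completeness: float,
                           rule: str = "rate") -> float:
    """Mean per-donor efficiency after bleaching each acceptor independently.

    Each discrete acceptor survives the bleach with probability
    ``1 - completeness``; the donor then transfers through the surviving
    paths only.  The expectation enumerates the survival patterns exactly.
    """
    c = float(completeness)
    if not 0.0 <= c <= 1.0:
        raise ValueError("bleach completeness must be within [0, 1]")
    paths = tuple(float(p) for p in paths)
    if not paths:
        return 0.0
    total = 0.0
    for alive in itertools.product((False, True), repeat=len(paths)):
        prob = math.prod((1.0 - c) if a else c for a in alive)
        if prob == 0.0:
            continue
        survivors = [p for p, a in zip(paths, alive) if a]
        total += prob * combine_acceptors(survivors, rule=rule)
    return total


def mean_post_bleach_efficiency(mix: SpeciesMix, completeness: float) -> float:
    """Donor-weighted mean efficiency of a mixture after acceptor bleaching."""
    d_tot = sum(s.weight * s.n_donors for s in mix.species)
    if d_tot == 0:
        return 0.0
    return sum(
        s.weight * s.n_donors
        * post_bleach_efficiency(s.paths, completeness, rule=mix.combine_rule)
        for s in mix.species
    ) / d_tot


def expected_bleach_increase(mix: SpeciesMix, params: FretParams,
                             bleach_completeness: float = 1.0) -> float:
    """Expected percent rise of donor fluorescence after acceptor bleaching.

    With complete bleach this is the algebraic identity ``100*E/(1-E)`` in the
    donor-weighted mean efficiency ``E``; partial bleach leaves each acceptor
    intact with probability ``1 - completeness`` before recomputing the donor
    signal.  Returns a percentage.
    """
    d_tot = sum(s.weight * s.n_donors for s in mix.species)
    if d_tot == 0:
        raise ValueError("mixture carries no donors; recovery undefined")
    e_pre = mix.mean_efficiency
    if e_pre >= 1.0 - 1e-12:
        raise SaturationError("mean efficiency of 1 implies infinite recovery")
    e_post = mean_post_bleach_efficiency(mix, bleach_completeness)
    return 100.0 * (e_pre - e_post) / (1.0 - e_pre)


def perturb_dimer_fraction(state: PopulationState, sd: float,
                           rng: np.random.Generator) -> PopulationState:
    """Biological replicate jitter: logit-normal draw around the dimer fraction.

    Models experiment-to-experiment variability of the dimer/monomer
    photo-equilibrium (UV dose, leaf age, expression timing).  ``sd`` is the
    standard deviation on the logit scale; 0 returns the state unchanged.
    """
    if sd < 0:
        raise ValueError("jitter sd must be >= 0")
    if sd == 0:
        return state
    df = min(max(state.resolved_dimer_fraction, 1e-6), 1.0 - 1e-6)
    logit = math.log(df / (1.0 - df)) + sd * float(rng.standard_normal())
    new_df = 1.0 / (1.0 + math.exp(-logit))
    if state.genotype == "constitutive_monomer":
        new_df = min(new_df, MONOMER_RESIDUAL_MAX)
    return replace(state, dimer_fraction=new_df)
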
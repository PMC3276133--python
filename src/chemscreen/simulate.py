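"""Synthetic cohorts for every pipeline stage.

The generator emulates the data-generating processes the analyses assume:

* competitive pooled growth of barcoded deletion strains over 20 wild-type
  generations with serial dilution every 5 generations (a strain of fitness
  f multiplies by 2^(g·f) over g pool generations);
* two-tag array readout with multiplicative lognormal intensity noise and a
  hard background floor on a 2^16 intensity scale;
* logistic OD600 growth curves sampled every 15 min over 24 h, with the
  exponential-phase rate encoding fitness (r = f·ln2/D_wt);
* Hill-type dose response of fitness (per-strain IC50, slope, floor);
* pathway-structured epistasis: double-mutant fitness
  W_xy = W_x·W_y + ε(pathway_x, pathway_y) + noise, built independently for
  both marker orientations.

Everything is driven by one integer seed: fixing it makes every emitted
table bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .growth import Condition, ODTimeSeries

__all__ = [
    "GenomeLayout",
    "NoiseModel",
    "SyntheticCohortSpec",
    "simulate_pool_growth",
    "simulate_tag_intensities",
    "simulate_growth_curves",
    "simulate_epistasis_cohort",
    "simulate_dose_response_fitness",
    "simulate_screen_arrays",
    "default_tag_map",
    "random_genome_layout",
    "preset_cohort",
]

INTENSITY_SCALE_MAX = float(2**16)
DEFAULT_BACKGROUND_FLOOR = float(2**6)


@dataclass
class GenomeLayout:
    """Ordered gene coordinates: 1-based inclusive, non-overlapping per
    chromosome, sorted by start; ``on_array`` marks genes probed by the
    array."""

    genes: pd.DataFrame  # gene_id, chromosome, start, end, strand, on_array

    REQUIRED = ("gene_id", "chromosome", "start", "end", "strand", "on_array")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.genes).reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"layout missing columns {missing}")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in layout")
        for chrom, sub in df.groupby("chromosome", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(np.diff(starts) <= 0):
                raise ValueError(f"chromosome {chrom}: genes not sorted by start")
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(f"chromosome {chrom}: overlapping genes")
            if np.any(starts < 1) or np.any(ends < starts):
                raise ValueError(f"chromosome {chrom}: bad 1-based coordinates")
        self.genes = df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeLayout":
        """Build from a possibly unsorted frame by sorting within
        chromosomes (chromosome order of first appearance is kept)."""
        order = {c: i for i, c in enumerate(pd.unique(df["chromosome"]))}
        df = df.sort_values(
            ["chromosome", "start"],
            key=lambda s: s.map(order) if s.name == "chromosome" else s,
            kind="stable",
        )
        return cls(df)

    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    def to_gff3(self, path) -> None:
        """Minimal GFF3 subset: gene features with ID and on_array attrs."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in self.genes.itertuples():
                attrs = f"ID={r.gene_id};on_array={'1' if r.on_array else '0'}"
                fh.write(
                    f"{r.chromosome}\tchemscreen\tgene\t{r.start}\t{r.end}\t.\t"
                    f"{r.strand}\t.\t{attrs}\n"
                )


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes used across the generator.

    intensity_cv: multiplicative lognormal CV of array intensities;
    od_sd: additive OD600 measurement noise; fitness_sd: replicate-level
    noise on fitness measurements (also applied per marker orientation).
    """

    intensity_cv: float = 0.3
    od_sd: float = 0.005
    fitness_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.od_sd < 0 or self.fitness_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class SyntheticCohortSpec:
    """Ground truth for a simulated strain cohort.

    ``true_fitness[strain][condition]`` is the dimensionless fitness W
    (wild type = 1).  ``dose_response[strain]`` is (IC50_mM, hill, floor)
    when a strain's fitness under a dosed condition should follow a Hill
    curve.  ``epsilon_rules[condition][(pathway_a, pathway_b)]`` is the
    additive ε offset planted between double mutants of those pathways
    (symmetric lookup; absent pairs mean ε = 0).
    """

    strain_ids: list[str]
    true_fitness: dict[str, dict[str, float]]
    pathway: dict[str, str] = field(default_factory=dict)
    epsilon_rules: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    dose_response: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    background_floor: float = DEFAULT_BACKGROUND_FLOOR
    seed: int = 0
    wildtype: str = "WT"
    d_wt_min: float = 90.0  # wild-type doubling time, minutes

    def __post_init__(self) -> None:
        for strain, conds in self.true_fitness.items():
            if strain not in self.strain_ids:
                raise ValueError(f"fitness given for unknown strain {strain!r}")
            for cond, w in conds.items():
                if w < 0:
                    raise ValueError(f"negative fitness for {strain!r} in {cond!r}")
        if self.d_wt_min <= 0:
            raise ValueError("wild-type doubling time must be positive")

    def fitness(self, strain: str, condition: str, dose_mm: float | None = None) -> float:
        """True fitness of a strain in a condition; falls back to the Hill
        dose response when a dose is given and the condition is unlisted."""
        if strain not in self.strain_ids:
            raise KeyError(f"unknown strain {strain!r}")
        conds = self.true_fitness.get(strain, {})
        if condition in conds:
            return conds[condition]
        if dose_mm is not None and strain in self.dose_response:
            ic50, h, floor = self.dose_response[strain]
            return hill_fitness(dose_mm, ic50, h, floor)
        if condition in ("YPD", "control"):
            return 1.0
        raise KeyError(f"no fitness defined for {strain!r} in {condition!r}")

    def epsilon_offset(self, condition: str, strain_x: str, strain_y: str) -> float:
        rules = self.epsilon_rules.get(condition, {})
        px = self.pathway.get(strain_x)
        py = self.pathway.get(strain_y)
        if px is None or py is None:
            return 0.0
        return rules.get((px, py), rules.get((py, px), 0.0))

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "strain_ids": list(self.strain_ids),
            "true_fitness": {s: dict(c) for s, c in self.true_fitness.items()},
            "pathway": dict(self.pathway),
            "epsilon_rules": {
                cond: {f"{a}|{b}": v for (a, b), v in rules.items()}
                for cond, rules in self.epsilon_rules.items()
            },
            "dose_response": {s: list(p) for s, p in self.dose_response.items()},
            "noise": {
                "intensity_cv": self.noise.intensity_cv,
                "od_sd": self.noise.od_sd,
                "fitness_sd": self.noise.fitness_sd,
            },
            "background_floor": self.background_floor,
            "seed": self.seed,
            "wildtype": self.wildtype,
            "d_wt_min": self.d_wt_min,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        noise = NoiseModel(**doc.get("noise", {}))
        eps = {
            cond: {tuple(k.split("|")): float(v) for k, v in rules.items()}
            for cond, rules in doc.get("epsilon_rules", {}).items()
        }
        return cls(
            strain_ids=list(doc["strain_ids"]),
            true_fitness={s: dict(c) for s, c in doc.get("true_fitness", {}).items()},
            pathway=dict(doc.get("pathway", {})),
            epsilon_rules=eps,
            dose_response={s: tuple(p) for s, p in doc.get("dose_response", {}).items()},
            noise=noise,
            background_floor=float(doc.get("background_floor", DEFAULT_BACKGROUND_FLOOR)),
            seed=int(doc.get("seed", 0)),
            wildtype=doc.get("wildtype", "WT"),
            d_wt_min=float(doc.get("d_wt_min", 90.0)),
        )


def hill_fitness(dose_mm: float, ic50: float, h: float, floor: float) -> float:
    """Hill-type fitness at a dose: floor + (1−floor)/(1 + (d/IC50)^h)."""
    if dose_mm <= 0:
        return 1.0
    return floor + (1.0 - floor) / (1.0 + (dose_mm / ic50) ** h)


# ---------------------------------------------------------------------------
# pooled growth


def simulate_pool_growth(
    spec: SyntheticCohortSpec,
    condition: str,
    *,
    generations: int = 20,
    n_dilutions: int = 4,
    pool_size: float = 1e7,
    start_cv: float = 0.25,
    strains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Competitive pooled growth with serial dilutions.

    A strain of fitness f multiplies by 2^(g·f) over g pool (= wild-type)
    generations.  The pool is diluted back to ``pool_size`` cells after
    every ``generations / n_dilutions`` generations, which leaves relative
    abundances untouched.  Starting abundances are lognormal with CV
    ``start_cv`` (set 0 for an even pool).  Returns strains × generation
    checkpoints (0, step, ..., generations), abundances in cells.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    if n_dilutions <= 0 or generations % n_dilutions != 0:
        raise ValueError("generations must divide evenly into dilution epochs")
    strains = list(strains) if strains is not None else list(spec.strain_ids)
    f = np.array([spec.fitness(s, condition) for s in strains])

    rng = np.random.default_rng(spec.seed)
    if start_cv > 0:
        sigma = math.sqrt(math.log(1.0 + start_cv**2))
        a = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(strains))
    else:
        a = np.ones(len(strains))
    a = a / a.sum() * pool_size

    step = generations // n_dilutions
    checkpoints = [0]
    table = [a.copy()]
    for _ in range(n_dilutions):
        a = a * np.exp2(step * f)
        a = a / a.sum() * pool_size  # dilution back to constant pool size
        checkpoints.append(checkpoints[-1] + step)
        table.append(a.copy())
    return pd.DataFrame(
        np.column_stack(table), index=pd.Index(strains, name="strain"),
        columns=pd.Index(checkpoints, name="generation"),
    )


# ---------------------------------------------------------------------------
# array intensities


def default_tag_map(strains: Sequence[str]):
    """Systematic up/down tag names for a strain list."""
    from .screen import TagMap

    return TagMap({s: (f"{s}_up", f"{s}_dn") for s in strains})


def simulate_tag_intensities(
    abundances: pd.Series,
    tag_map,
    *,
    intensity_cv: float = 0.3,
    background_floor: float = DEFAULT_BACKGROUND_FLOOR,
    scale: float | None = None,
    seed: int | None = None,
    array_id: str = "array1",
    role: str = "control",
):
    """Array readout of a strain-abundance vector.

    Each strain's up and down tags independently report
    max(floor, scale·abundance·lognormal), the lognormal having unit mean
    and the given CV.  ``scale`` defaults to putting the median strain at
    2^12 on the 2^16 intensity scale.  Raises if any strain lacks a tag
    assignment.
    """
    from .screen import ArraySample

    abundances = pd.Series(abundances, dtype=float)
    if (abundances < 0).any():
        raise ValueError("abundances must be non-negative")
    missing = [s for s in abundances.index if s not in tag_map.tags]
    if missing:
        raise ValueError(f"strains without tag assignment: {missing[:10]}")
    if scale is None:
        med = float(abundances[abundances > 0].median())
        scale = (2.0**12) / med if med > 0 else 1.0

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + intensity_cv**2)) if intensity_cv > 0 else 0.0
    values: dict[str, float] = {}
    for strain in abundances.index:
        up, dn = tag_map.tags[strain]
        for tag in (up, dn):
            if tag is None:
                continue
            noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
            values[tag] = max(background_floor, scale * abundances[strain] * noise)
    return ArraySample(
        array_id=array_id,
        role=role,
        intensities=pd.Series(values),
    )


def simulate_screen_arrays(
    spec: SyntheticCohortSpec,
    condition: str,
    *,
    n_controls: int = 2,
    n_treatments: int = 2,
    generations: int = 20,
    n_dilutions: int = 4,
    control_condition: str = "control",
    scale: float | None = None,
) -> list:
    """Full pooled-screen input set: control and treatment arrays from
    independent pool growths read out with tag noise.

    Each replicate array derives from its own pool simulation (seeded
    deterministically from ``spec.seed``) so biological and array noise
    both enter, as in a real multi-replicate screen.
    """
    tag_map = default_tag_map(spec.strain_ids)
    samples = []
    for i in range(n_controls + n_treatments):
        role = "control" if i < n_controls else "treatment"
        cond = control_condition if role == "control" else condition
        sub = SyntheticCohortSpec(
            strain_ids=spec.strain_ids,
            true_fitness=spec.true_fitness,
            pathway=spec.pathway,
            epsilon_rules=spec.epsilon_rules,
            dose_response=spec.dose_response,
            noise=spec.noise,
            background_floor=spec.background_floor,
            seed=spec.seed * 1000 + i,
            wildtype=spec.wildtype,
            d_wt_min=spec.d_wt_min,
        )
        pool = simulate_pool_growth(
            sub, cond, generations=generations, n_dilutions=n_dilutions
        )
        final = pool.iloc[:, -1]
        samples.append(
            simulate_tag_intensities(
                final,
                tag_map,
                intensity_cv=spec.noise.intensity_cv,
                background_floor=spec.background_floor,
                scale=scale,
                seed=spec.seed * 1000 + 500 + i,
                array_id=f"{role}{i+1}",
                role=role,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# growth curves


def simulate_growth_curves(
    spec: SyntheticCohortSpec,
    condition: Condition | str,
    *,
    strains: Sequence[str] | None = None,
    sampling_interval_min: float = 15.0,
    duration_h: float = 24.0,
    od0: float = 0.05,
    carrying_capacity: float = 1.0,
    replicates: int = 1,
) -> list[ODTimeSeries]:
    """Logistic OD600 trajectories sampled on a fixed grid.

    Each strain grows logistically with rate r = f·ln2/D_wt, so the
    noiseless wild type doubles every configured D_wt minutes in early
    exponential phase.  Additive Gaussian measurement noise (clipped at 0)
    with SD ``spec.noise.od_sd`` is applied per reading.
    """
    if spec.d_wt_min <= 0:
        raise ValueError("wild-type doubling time must be positive")
    total_min = duration_h * 60.0
    n_steps = total_min / sampling_interval_min
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("duration must be a multiple of the sampling interval")
    times = np.arange(round(n_steps) + 1) * sampling_interval_min

    cond = (
        condition
        if isinstance(condition, Condition)
        else Condition(medium=condition)
    )
    strains = list(strains) if strains is not None else list(spec.strain_ids)
    rng = np.random.default_rng(spec.seed + 7)
    out: list[ODTimeSeries] = []
    K = carrying_capacity
    for strain in strains:
        f = spec.fitness(strain, cond.label() if isinstance(condition, Condition) else condition,
                         dose_mm=cond.dose_mm if cond.compound else None)
        r = f * math.log(2.0) / spec.d_wt_min
        with np.errstate(over="ignore"):
            growth = od0 * K / (od0 + (K - od0) * np.exp(-r * times))
        if f == 0:
            growth = np.full_like(times, od0)
        for rep in range(replicates):
            od = growth.copy()
            if spec.noise.od_sd > 0:
                od = np.clip(od + rng.normal(0, spec.noise.od_sd, od.shape), 0, None)
            out.append(
                ODTimeSeries(
                    well=f"{strain}_r{rep+1}",
                    strain=strain,
                    condition=cond,
                    times=times,
                    readings=od,
                )
            )
    return out


def simulate_dose_response_fitness(
    *,
    ic50: float,
    hill: float = 2.0,
    floor: float = 0.05,
    doses: Sequence[float],
    sd: float = 0.05,
    replicates: int = 3,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy fitness measurements along a dose sweep (truth = Hill curve).

    Returns flat (doses, fitness) arrays with ``replicates`` values per
    dose; Gaussian noise clipped at zero.
    """
    rng = np.random.default_rng(seed)
    d = np.repeat(np.asarray(doses, dtype=float), replicates)
    truth = np.array([hill_fitness(x, ic50, hill, floor) for x in d])
    f = np.clip(truth + rng.normal(0, sd, truth.shape), 0.0, None)
    return d, f


# ---------------------------------------------------------------------------
# epistasis cohorts


def simulate_epistasis_cohort(
    spec: SyntheticCohortSpec,
    conditions: Sequence[str],
    *,
    pairs: Sequence[tuple[str, str]] | None = None,
    orientation_disagreement: Mapping[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Double-mutant fitness for both marker orientations plus truth.

    For each unordered pair and condition, both orientations independently
    measure W_xy = W_x·W_y + ε(pathway_x, pathway_y) + N(0, fitness_sd),
    clipped at 0.  ``orientation_disagreement`` optionally injects a fixed
    offset split between the two orientations of selected pairs (for
    filter testing).  Returns (doubles, singles, truth): doubles has
    columns gene_x, gene_y, orientation (KanNat/NatKan), condition, W;
    singles has gene, condition, W (measured with the same noise); truth
    has the planted ε per pair and condition.
    """
    strains = [s for s in spec.strain_ids if s != spec.wildtype]
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(strains) for b in strains[i + 1 :]]
    disagreement = dict(orientation_disagreement or {})
    rng = np.random.default_rng(spec.seed + 13)
    sd = spec.noise.fitness_sd

    singles_rows = []
    for cond in conditions:
        for s in strains:
            w = spec.fitness(s, cond)
            noisy = max(0.0, w + (rng.normal(0, sd) if sd > 0 else 0.0))
            singles_rows.append({"gene": s, "condition": cond, "W": noisy})

    doubles_rows = []
    truth_rows = []
    for cond in conditions:
        for x, y in pairs:
            wx = spec.fitness(x, cond)
            wy = spec.fitness(y, cond)
            eps = spec.epsilon_offset(cond, x, y)
            truth_rows.append(
                {"gene_x": x, "gene_y": y, "condition": cond,
                 "W_x": wx, "W_y": wy, "epsilon_true": eps}
            )
            delta = disagreement.get((x, y), disagreement.get((y, x), 0.0))
            for orientation, off in (("KanNat", +0.5 * delta), ("NatKan", -0.5 * delta)):
                w = wx * wy + eps + off
                if sd > 0:
                    w += rng.normal(0, sd)
                doubles_rows.append(
                    {
                        "gene_x": x,
                        "gene_y": y,
                        "orientation": orientation,
                        "condition": cond,
                        "W": max(0.0, w),
                    }
                )
    return (
        pd.DataFrame(doubles_rows),
        pd.DataFrame(singles_rows),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# layouts and presets


def random_genome_layout(
    gene_ids: Sequence[str],
    *,
    n_chromosomes: int = 3,
    off_array: Iterable[str] = (),
    gene_length: int = 1000,
    gap: int = 200,
    seed: int | None = None,
) -> GenomeLayout:
    """Tile genes across chromosomes in the given order with fixed spacing;
    chromosome breakpoints are drawn at random when a seed is given, else
    genes are split evenly."""
    gene_ids = list(gene_ids)
    off = set(off_array)
    n = len(gene_ids)
    rng = np.random.default_rng(seed)
    if seed is not None and n_chromosomes > 1:
        cuts = np.sort(rng.choice(np.arange(1, n), size=n_chromosomes - 1, replace=False))
    else:
        cuts = np.linspace(0, n, n_chromosomes + 1).astype(int)[1:-1]
    bounds = [0, *cuts.tolist(), n]
    rows = []
    for ci in range(len(bounds) - 1):
        pos = 1
        for g in gene_ids[bounds[ci] : bounds[ci + 1]]:
            rows.append(
                {
                    "gene_id": g,
                    "chromosome": f"chr{ci+1:02d}",
                    "start": pos,
                    "end": pos + gene_length - 1,
                    "strand": "+",
                    "on_array": g not in off,
                }
            )
            pos += gene_length + gap
    return GenomeLayout(pd.DataFrame(rows))


def preset_cohort(name: str, seed: int = 0) -> SyntheticCohortSpec:
    """Ready-made cohorts matching the study designs.

    ``dsp``: 400 deletion strains, 20 spiked sensitive (W = 0.8 under
    treatment) for the sensitivity screen.  ``msp``: 60-gene genomic
    library cohort with two planted resistant loci (use with
    ``random_genome_layout``).  ``epistasis``: 10 deletion strains in two
    pathways with within-pathway alleviation (+0.15) and cross-pathway
    aggravation (−0.10) under treatment only.  ``growth``: wild type plus
    graded-fitness strains with Hill dose responses (IC50 8.6 and 45.5 mM).
    """
    if name == "dsp":
        strains = [f"strain{i:03d}" for i in range(400)]
        sens = strains[:20]
        fitness = {
            s: {"control": 1.0, "treatment": 0.8 if s in sens else 1.0}
            for s in strains
        }
        return SyntheticCohortSpec(
            strain_ids=strains, true_fitness=fitness, seed=seed, wildtype="none"
        )
    if name == "msp":
        strains = [f"orf{i:03d}" for i in range(60)]
        resistant = strains[10:13] + strains[40:42]
        fitness = {
            s: {"control": 1.0, "treatment": 1.3 if s in resistant else 0.4}
            for s in strains
        }
        return SyntheticCohortSpec(
            strain_ids=strains, true_fitness=fitness, seed=seed, wildtype="none"
        )
    if name == "epistasis":
        genes = [f"gene{i:02d}" for i in range(10)]
        strains = ["WT", *genes]
        rng = np.random.default_rng(seed)
        fitness = {"WT": {"control": 1.0, "treatment": 1.0}}
        for g in genes:
            fitness[g] = {
                "control": 1.0,
                "treatment": float(rng.uniform(0.5, 0.95)),
            }
        pathway = {g: ("A" if i < 5 else "B") for i, g in enumerate(genes)}
        rules = {
            "treatment": {
                ("A", "A"): 0.15,
                ("B", "B"): 0.15,
                ("A", "B"): -0.10,
            }
        }
        return SyntheticCohortSpec(
            strain_ids=strains,
            true_fitness=fitness,
            pathway=pathway,
            epsilon_rules=rules,
            noise=NoiseModel(fitness_sd=0.02),
            seed=seed,
        )
    if name == "growth":
        strains = ["WT", "slow", "half", "dead"]
        fitness = {
            "WT": {"YPD": 1.0},
            "slow": {"YPD": 0.8},
            "half": {"YPD": 0.5},
            "dead": {"YPD": 0.0},
        }
        dose = {s: (8.6, 2.0, 0.05) for s in strains}
        return SyntheticCohortSpec(
            strain_ids=strains,
            true_fitness=fitness,
            dose_response=dose,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose dsp, msp, epistasis, growth")
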
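"""Synthetic Ct datasets, intensity matrices and dilution series with known truth.

The generators emulate a reference-gene validation study: a panel of ~23
candidate genes measured by qRT-PCR across 9 cell lines with 3 biological x
3 technical replicates, expression microarrays of the same lines across 48
arrays, and serial-dilution standard curves — but with *designed* per-gene
noise levels, condition effects and evenness profiles, so that every
downstream ranking can be checked against ground truth.

Ct noise model (additive Gaussian on the Ct scale)::

    ct(g, u, t) = baseline_g + condition_effect_g(cond(u)) + s_u + e_gu + tau_gut

with ``s_u ~ N(0, sigma_sample)`` shared by all genes in unit u (the
loading/RT component that reference-gene normalization removes),
``e_gu ~ N(0, sigma_gene_g)`` the gene's own biological instability, and
``tau ~ N(0, sigma_tech)`` the technical replicate error.

The intensity generator constructs each gene's array profile so that the
*realized* gene-level mean, CV and MFC equal the designed targets (endpoint
pinning plus a one-dimensional root-find on the interior spread), then
splits the profile across probes in one of three modes:

* ``proportional`` — constant shares; probes inherit the gene's CV/MFC,
* ``compensating`` — per-array random shares; probes are individually noisy
  but sum exactly to the even gene profile,
* ``divergent`` — each probe gets its own designed profile; the gene-level
  row is whatever the probes sum to.

Every generator is deterministic given (design, seed); per-gene substreams
mean that adding a gene to a design does not perturb the other genes' draws.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datamodel import CT_MAX, CtDataset, DilutionSeries, IntensityMatrix

__all__ = [
    "GeneDesign",
    "SampleDesign",
    "CtSimulationDesign",
    "IntensityGeneDesign",
    "IntensitySimulationDesign",
    "simulate_ct_dataset",
    "simulate_intensity_matrix",
    "simulate_dilution_series",
    "simulate_perturbation_experiment",
    "study_ct_design",
    "recovery_ct_design",
    "study_intensity_design",
]


# ---------------------------------------------------------------------------
# Ct simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneDesign:
    gene_id: str
    baseline_ct: float
    sigma_gene: float = 0.0
    condition_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    n_bio: int = 3
    n_tech: int = 3
    condition: str | None = None


@dataclasses.dataclass(frozen=True)
class CtSimulationDesign:
    genes: tuple[GeneDesign, ...]
    samples: tuple[SampleDesign, ...]
    sigma_sample: float = 0.3
    sigma_tech: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genes) < 3:
            raise ValueError("a Ct design needs >= 3 genes")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        n_units = sum(s.n_bio for s in self.samples)
        if n_units < 2:
            raise ValueError("a Ct design needs >= 2 biological units")
        for g in self.genes:
            if not 15.0 <= g.baseline_ct <= 35.0:
                raise ValueError(
                    f"baseline Ct {g.baseline_ct} of {g.gene_id!r} outside [15, 35]"
                )
            if g.sigma_gene < 0:
                raise ValueError("sigma_gene must be >= 0")
        if self.sigma_sample < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be >= 0")


def design_from_dict(tree: Mapping) -> CtSimulationDesign:
    """Build a Ct simulation design from a plain key-value tree.

    The tree (e.g. parsed from YAML/TOML/JSON) has the shape::

        genes:
          - {gene_id: ACTB, baseline_ct: 18.0, sigma_gene: 0.2,
             condition_effects: {sorafenib: 0.5}}
        samples:
          - {sample_id: CL1, n_bio: 3, n_tech: 3, condition: control}
        sigma_sample: 0.3
        sigma_tech: 0.1
        seed: 0
    """
    genes = tuple(
        GeneDesign(
            gene_id=str(g["gene_id"]),
            baseline_ct=float(g["baseline_ct"]),
            sigma_gene=float(g.get("sigma_gene", 0.0)),
            condition_effects={
                str(k): float(v)
                for k, v in dict(g.get("condition_effects", {})).items()
            },
        )
        for g in tree["genes"]
    )
    samples = tuple(
        SampleDesign(
            sample_id=str(s["sample_id"]),
            n_bio=int(s.get("n_bio", 3)),
            n_tech=int(s.get("n_tech", 3)),
            condition=s.get("condition"),
        )
        for s in tree["samples"]
    )
    return CtSimulationDesign(
        genes,
        samples,
        sigma_sample=float(tree.get("sigma_sample", 0.3)),
        sigma_tech=float(tree.get("sigma_tech", 0.1)),
        seed=int(tree.get("seed", 0)),
    )


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene substream, stable under changes to the rest of the design."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, zlib.crc32(gene_id.encode())))
    )


def simulate_ct_dataset(
    design: CtSimulationDesign,
) -> tuple[CtDataset, pd.DataFrame]:
    """Draw a Ct dataset from the additive Gaussian model.

    Returns the dataset plus a ground-truth table with, per gene, the
    designed baseline, sigma_gene, the spread (population SD over units) of
    its condition effects, and the designed total instability
    ``sqrt(sigma_gene**2 + condition_spread**2)``.
    """
    units: list[tuple[str, int, str | None]] = []
    for s in design.samples:
        for b in range(1, s.n_bio + 1):
            units.append((s.sample_id, b, s.condition))

    rng_units = np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(0,))
    )
    s_u = rng_units.normal(0.0, design.sigma_sample, size=len(units))

    rows = []
    truth_rows = []
    cond_of_unit = np.array(
        [c if c is not None else "" for (_, _, c) in units], dtype=object
    )
    for g in design.genes:
        rng = _gene_rng(design.seed, g.gene_id)
        e_gu = rng.normal(0.0, g.sigma_gene, size=len(units))
        cond_shift = np.array(
            [g.condition_effects.get(c, 0.0) if c else 0.0 for c in cond_of_unit]
        )
        for iu, (sample_id, bio, cond) in enumerate(units):
            n_tech = next(
                s.n_tech for s in design.samples if s.sample_id == sample_id
            )
            tau = rng.normal(0.0, design.sigma_tech, size=n_tech)
            base = g.baseline_ct + cond_shift[iu] + s_u[iu] + e_gu[iu]
            for t in range(1, n_tech + 1):
                ct = float(np.clip(base + tau[t - 1], 0.05, CT_MAX))
                rows.append(
                    {
                        "gene": g.gene_id,
                        "sample": sample_id,
                        "bio_rep": bio,
                        "tech_rep": t,
                        "ct": ct,
                        "condition": cond,
                        "group": None,
                    }
                )
        spread = float(np.std(cond_shift))  # population SD over units
        truth_rows.append(
            {
                "gene": g.gene_id,
                "baseline_ct": g.baseline_ct,
                "sigma_gene": g.sigma_gene,
                "condition_spread": spread,
                "designed_instability": math.hypot(g.sigma_gene, spread),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return CtDataset(pd.DataFrame(rows)), truth


def simulate_perturbation_experiment(
    base_design: CtSimulationDesign,
    perturbations: Sequence[str],
    affected_genes: Mapping[str, Mapping[str, float]],
) -> dict[str, tuple[CtDataset, pd.DataFrame]]:
    """Control + perturbed Ct dataset per perturbation.

    ``base_design.samples`` define the control condition (label
    ``'control'``); for each perturbation the same samples are re-measured
    under the perturbation label, with the designed per-gene Ct shifts from
    ``affected_genes`` applied.  Condition labels serve directly as
    NormFinder groups and as the treated/control contrast for fold changes.
    """
    known = {g.gene_id for g in base_design.genes}
    missing = sorted(set(affected_genes) - known)
    if missing:
        raise ValueError(f"affected genes absent from base design: {missing}")

    out: dict[str, tuple[CtDataset, pd.DataFrame]] = {}
    for i, pert in enumerate(perturbations):
        genes = tuple(
            dataclasses.replace(
                g,
                condition_effects={
                    **dict(g.condition_effects),
                    pert: affected_genes.get(g.gene_id, {}).get(pert, 0.0),
                },
            )
            for g in base_design.genes
        )
        samples = tuple(
            dataclasses.replace(s, condition="control") for s in base_design.samples
        ) + tuple(
            dataclasses.replace(s, condition=pert) for s in base_design.samples
        )
        sub_seed = int(
            np.random.SeedSequence(
                entropy=base_design.seed, spawn_key=(2, i)
            ).generate_state(1)[0] % (2**31)
        )
        design = dataclasses.replace(
            base_design, genes=genes, samples=samples, seed=sub_seed
        )
        out[pert] = simulate_ct_dataset(design)
    return out


# ---------------------------------------------------------------------------
# Intensity simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class IntensityGeneDesign:
    gene_id: str
    n_probes: int = 1
    mean_intensity: float = 2000.0
    cv_target: float = 0.05
    mfc_target: float = 1.2
    probe_mode: str = "proportional"  # proportional | compensating | divergent
    probe_targets: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.mean_intensity <= 0:
            raise ValueError("mean_intensity must be > 0")
        if not 0.0 <= self.cv_target < 1.0:
            raise ValueError("cv_target must be in [0, 1)")
        if self.mfc_target < 1.0:
            raise ValueError("mfc_target must be >= 1")
        if (self.cv_target == 0.0) != (self.mfc_target == 1.0):
            raise ValueError(
                f"{self.gene_id!r}: cv_target 0 and mfc_target 1 must "
                "co-occur (a constant row has both)"
            )
        if self.probe_mode == "divergent" and (
            self.probe_targets is None or len(self.probe_targets) != self.n_probes
        ):
            raise ValueError(
                f"{self.gene_id!r}: divergent mode needs one (mean, cv, mfc) "
                "target per probe"
            )


@dataclasses.dataclass(frozen=True)
class IntensitySimulationDesign:
    genes: tuple[IntensityGeneDesign, ...]
    n_arrays: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_arrays < 2:
            raise ValueError("need >= 2 arrays")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")


_RESAMPLE_CAP = 50


def _profile_with_exact_stats(
    rng: np.random.Generator, n: int, mean: float, cv: float, mfc: float,
    label: str,
) -> np.ndarray:
    """Array profile whose realized mean, CV (ddof=1) and MFC hit the targets.

    The shape is ``y = 1 + (mfc - 1) * u`` with u in [0, 1], the minimum
    pinned at 0 and the maximum at 1 (MFC exact by construction).  Interior
    points are pulled toward or pushed away from their own mean by a factor
    t (clipped to [0, 1]); CV is continuous and increasing in t, so the
    target is located by bisection.  Shapes that cannot reach the target CV
    are redrawn up to a cap, then rejected.
    """
    if cv == 0.0:
        return np.full(n, mean)
    if n < 3:
        raise ValueError(f"{label}: need >= 3 arrays for a non-constant target")

    def realized_cv(u: np.ndarray) -> float:
        y = 1.0 + (mfc - 1.0) * u
        return float(y.std(ddof=1) / y.mean())

    for _ in range(_RESAMPLE_CAP):
        interior = rng.uniform(0.05, 0.95, size=n - 2)
        pos = rng.permutation(n)
        m = interior.mean()

        def u_of_t(t: float) -> np.ndarray:
            vals = np.clip(m + t * (interior - m), 0.0, 1.0)
            u = np.empty(n)
            u[pos[0]] = 0.0
            u[pos[1]] = 1.0
            u[pos[2:]] = vals
            return u

        t_hi = 5000.0
        lo, hi = realized_cv(u_of_t(0.0)), realized_cv(u_of_t(t_hi))
        if not (lo <= cv <= hi):
            continue
        t_star = optimize.brentq(
            lambda t: realized_cv(u_of_t(t)) - cv, 0.0, t_hi, xtol=1e-13
        )
        y = 1.0 + (mfc - 1.0) * u_of_t(t_star)
        return y * (mean / y.mean())
    raise ValueError(
        f"{label}: cv={cv} unreachable with mfc={mfc} at n={n} "
        f"after {_RESAMPLE_CAP} shape draws"
    )


def _strict_pass(mean: float, cv: float, mfc: float) -> dict[str, bool]:
    # the generator's own labelling of the standard evenness cutoffs;
    # kept inline so it is an independent path from the preselection module
    flags = {"cv_ok": cv < 0.11, "intensity_ok": mean > 1000.0, "mfc_ok": mfc < 1.4}
    flags["passes"] = all(flags.values())
    return flags


def _row_stats(row: np.ndarray) -> tuple[float, float, float]:
    mean = float(row.mean())
    return mean, float(row.std(ddof=1) / mean), float(row.max() / row.min())


def simulate_intensity_matrix(
    design: IntensitySimulationDesign,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Draw a probe x array intensity matrix with designed evenness profiles.

    Returns the matrix plus a ground-truth table with one row per gene:
    realized gene-level mean/CV/MFC, the standard-cutoff pass flags at gene
    level, probe level (any-probe and all-probe rules), and their
    intersection — computed by the generator itself from the realized
    matrix, independently of the preselection module.
    """
    arrays = [f"A{i + 1:02d}" for i in range(design.n_arrays)]
    probe_rows: dict[str, np.ndarray] = {}
    probe_to_gene: dict[str, str] = {}
    truth_rows = []

    for g in design.genes:
        rng = _gene_rng(design.seed, g.gene_id)
        if g.probe_mode == "divergent":
            probes = [
                _profile_with_exact_stats(
                    rng, design.n_arrays, pm, pcv, pmfc, f"{g.gene_id}/probe{p}"
                )
                for p, (pm, pcv, pmfc) in enumerate(g.probe_targets, 1)
            ]
        else:
            y = _profile_with_exact_stats(
                rng, design.n_arrays, g.mean_intensity, g.cv_target,
                g.mfc_target, g.gene_id,
            )
            if g.n_probes == 1:
                probes = [y]
            elif g.probe_mode == "proportional":
                shares = np.full(g.n_probes, 1.0 / g.n_probes)
                probes = [share * y for share in shares]
            elif g.probe_mode == "compensating":
                # per-array random shares: probes wobble, the sum stays even
                shares = rng.dirichlet(
                    np.full(g.n_probes, 2.0), size=design.n_arrays
                ).T  # probes x arrays
                probes = [shares[p] * y for p in range(g.n_probes)]
            else:
                raise ValueError(f"unknown probe_mode {g.probe_mode!r}")

        probe_ids = [f"{g.gene_id}_p{p + 1}" for p in range(len(probes))]
        for pid, row in zip(probe_ids, probes):
            probe_rows[pid] = row
            probe_to_gene[pid] = g.gene_id

        gene_row = np.sum(probes, axis=0)
        gmean, gcv, gmfc = _row_stats(gene_row)
        gene_flags = _strict_pass(gmean, gcv, gmfc)
        probe_flags = [_strict_pass(*_row_stats(r))["passes"] for r in probes]
        truth_rows.append(
            {
                "gene": g.gene_id,
                "mean_intensity": gmean,
                "cv": gcv,
                "mfc": gmfc,
                "gene_pass": gene_flags["passes"],
                "probe_pass_any": any(probe_flags),
                "probe_pass_all": all(probe_flags),
                "both_pass": gene_flags["passes"] and any(probe_flags),
            }
        )

    values = pd.DataFrame.from_dict(probe_rows, orient="index", columns=arrays)
    return (
        IntensityMatrix(values, probe_to_gene),
        pd.DataFrame(truth_rows).set_index("gene"),
    )


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------

def simulate_dilution_series(
    efficiency: float = 1.0,
    top_ct: float = 18.0,
    n_steps: int = 5,
    dilution_factor: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DilutionSeries:
    """Serial-dilution Ct readings at a given amplification efficiency.

    Each dilution step multiplies input by ``1/dilution_factor``, so Ct
    rises by ``log(dilution_factor) / log(1 + efficiency)`` cycles per step
    (exactly log2(5) ~ 2.3219 for five-fold dilutions at 100% efficiency).
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    if n_steps < 3:
        raise ValueError("need >= 3 dilution steps")
    rng = np.random.default_rng(seed)
    step_ct = math.log(dilution_factor) / math.log(1.0 + efficiency)
    points = [
        (k, top_ct + k * step_ct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
        for k in range(n_steps)
    ]
    return DilutionSeries(points, dilution_factor)


# ---------------------------------------------------------------------------
# Study-scale default designs
# ---------------------------------------------------------------------------

def study_ct_design(
    seed: int = 0,
    n_genes: int = 23,
    n_samples: int = 9,
    sigma_gene: Sequence[float] | None = None,
    sigma_sample: float = 0.3,
    sigma_tech: float = 0.1,
) -> CtSimulationDesign:
    """A candidate-panel design at study scale: 23 genes, 9 cell lines, 3x3.

    Baselines are spread over the typical qPCR abundance range (Ct 17-31);
    per-gene sigmas default to an even spread from 0.1 to 1.0 cycles.
    """
    if sigma_gene is None:
        sigma_gene = np.linspace(0.1, 1.0, n_genes)
    if len(sigma_gene) != n_genes:
        raise ValueError("sigma_gene length must equal n_genes")
    baselines = np.linspace(17.0, 31.0, n_genes)
    genes = tuple(
        GeneDesign(f"REF{i + 1:02d}", float(baselines[i]), float(sigma_gene[i]))
        for i in range(n_genes)
    )
    samples = tuple(SampleDesign(f"CL{i + 1}") for i in range(n_samples))
    return CtSimulationDesign(genes, samples, sigma_sample, sigma_tech, seed)


def recovery_ct_design(seed: int = 0, stable_gene: str = "REF12") -> CtSimulationDesign:
    """The parameter-recovery benchmark: one near-perfect gene in a 23-gene panel.

    One designated gene has sigma_gene = 0.05 cycles; the other 22 span
    0.4-1.2 cycles, so every method should identify the designed gene as the
    most stable.
    """
    base = study_ct_design(seed)
    others = iter(np.linspace(0.4, 1.2, len(base.genes) - 1))
    genes = tuple(
        dataclasses.replace(
            g, sigma_gene=0.05 if g.gene_id == stable_gene else float(next(others))
        )
        for g in base.genes
    )
    if stable_gene not in {g.gene_id for g in genes}:
        raise ValueError(f"{stable_gene!r} not in the panel")
    return dataclasses.replace(base, genes=genes)


def study_intensity_design(seed: int = 0, n_arrays: int = 48) -> IntensitySimulationDesign:
    """An array-screen design with >= 200 genes covering every pass category.

    Cycles through: clean pass-both genes, pass-gene-only genes (probes
    compensate each other or fall below the intensity cutoff), pass-probe-
    only genes (one even probe next to a wild one), fail-everything genes,
    plus strict-cutoff boundary genes a hair outside CV 0.11, MFC 1.4 and
    mean 1000, and just-inside neighbours.
    """
    rng = np.random.default_rng(seed)
    genes: list[IntensityGeneDesign] = []

    def gid() -> str:
        return f"G{len(genes) + 1:03d}"

    def cv_for(mfc: float, lo_frac: float, hi_frac: float) -> float:
        # achievable CVs are bounded by (mfc-1)/(mfc+1); sample inside it
        bound = (mfc - 1.0) / (mfc + 1.0)
        return float(rng.uniform(lo_frac, hi_frac) * bound)

    for _ in range(60):  # pass both levels: even, strong, probes each > 1000
        mfc = float(rng.uniform(1.15, 1.3))
        genes.append(
            IntensityGeneDesign(
                gid(), n_probes=2,
                mean_intensity=float(rng.uniform(3000, 8000)),
                cv_target=cv_for(mfc, 0.35, 0.7), mfc_target=mfc,
            )
        )
    for _ in range(45):  # gene-level only: even sum, noisy individual probes
        mfc = float(rng.uniform(1.15, 1.3))
        genes.append(
            IntensityGeneDesign(
                gid(), n_probes=2, probe_mode="compensating",
                mean_intensity=float(rng.uniform(3000, 6000)),
                cv_target=cv_for(mfc, 0.35, 0.7), mfc_target=mfc,
            )
        )
    for _ in range(45):  # probe-level only: one even probe beside a wild one
        mfc_even = float(rng.uniform(1.15, 1.3))
        mfc_wild = float(rng.uniform(2.5, 4.0))
        genes.append(
            IntensityGeneDesign(
                gid(), n_probes=2, probe_mode="divergent",
                probe_targets=(
                    (float(rng.uniform(1500, 3000)),
                     cv_for(mfc_even, 0.35, 0.7), mfc_even),
                    (float(rng.uniform(3000, 6000)),
                     cv_for(mfc_wild, 0.5, 0.8), mfc_wild),
                ),
            )
        )
    for _ in range(44):  # fail everywhere: weak and/or wildly varying
        mfc = float(rng.uniform(2.0, 3.5))
        genes.append(
            IntensityGeneDesign(
                gid(), n_probes=1,
                mean_intensity=float(rng.uniform(100, 600)),
                cv_target=cv_for(mfc, 0.5, 0.8), mfc_target=mfc,
            )
        )
    # boundary genes sit a hair's breadth (1e-9 relative) outside/inside the
    # strict cutoffs: far beyond any practical resolution, yet wide enough
    # that float summation-order effects (~1e-13) cannot flip the verdict
    eps = 1e-9
    boundary = [
        # a hair outside a strict cutoff -> must fail that check
        dict(mean_intensity=3000.0, cv_target=0.11 * (1 + eps), mfc_target=1.3),
        dict(mean_intensity=3000.0, cv_target=0.09, mfc_target=1.4 * (1 + eps)),
        dict(mean_intensity=1000.0 * (1 - eps), cv_target=0.05, mfc_target=1.2),
        # a hair inside every cutoff -> must pass
        dict(mean_intensity=3000.0, cv_target=0.11 * (1 - eps),
             mfc_target=1.4 * (1 - eps)),
        dict(mean_intensity=1000.0 * (1 + eps), cv_target=0.05, mfc_target=1.2),
        # low intensity but even (fails only the intensity cutoff)
        dict(mean_intensity=500.0, cv_target=0.05, mfc_target=1.2),
    ]
    for kw in boundary:
        genes.append(IntensityGeneDesign(gid(), n_probes=1, **kw))

    return IntensitySimulationDesign(tuple(genes), n_arrays=n_arrays, seed=seed)
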
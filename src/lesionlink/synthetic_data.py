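"""Truth-labelled synthetic study generator.

Emulates a two-laboratory factorial microarray study of the genotoxin MAM:
2 sites x 2 genotypes (wt, Mgmt-null) x 2 treatments (MAM, vehicle) x 4
timepoints x 3 arrays per cell, brain expression on a probe-level array
(11 probes per probeset) plus matched per-animal O6-mG lesion burdens in
brain and liver.  Planted treatment/genotype/interaction effects,
laboratory-inconsistent probesets, and lesion-anchored probesets are all
recorded in a truth-label table so downstream stages can be scored.

Lesion time-courses follow a single-pulse first-order-repair model: the
expected burden is ``initial * exp(-repair_rate * t)`` with a lognormal
measurement error, left-censored at the assay's minimal detectable
quantity (MDQ).  The repair rate is genotype-dependent (lower without a
functional Mgmt gene), which qualitatively reproduces a flat/low wild-type
brain curve and persistently elevated knockout burdens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ExpressionMatrix

__all__ = [
    "StudyDesign",
    "EffectSpec",
    "LesionKinetics",
    "lesion_timecourse",
    "generate_study",
    "SimulatedStudy",
    "StudySimulator",
    "generate_promoters",
    "generate_gene_sets",
]

TRUTH_CATEGORIES = ("treatment", "genotype", "interaction", "lab_inconsistent", "anchored")

# optical background added to raw intensities (mean, sd); matches the
# normal-noise component assumed by RMA background correction
_OPTICAL_BG_MEAN = 100.0
_OPTICAL_BG_SD = 20.0


@dataclass
class StudyDesign:
    """Factorial layout of the two-site study."""

    sites: tuple = ("siteA", "siteB")
    genotypes: tuple = ("wt", "ko")
    treatments: tuple = ("MAM", "vehicle")
    timepoints_h: tuple = (6, 24, 48, 168)
    arrays_per_cell: int = 3
    tissues: tuple = ("brain", "liver")
    probes_per_probeset: int = 11
    n_probesets: int = 1000

    def __post_init__(self) -> None:
        if len(self.sites) != 2:
            raise ValueError("design requires exactly 2 sites")
        if list(self.timepoints_h) != sorted(set(self.timepoints_h)):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("arrays_per_cell", "probes_per_probeset", "n_probesets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_arrays(self) -> int:
        return (len(self.sites) * len(self.genotypes) * len(self.treatments)
                * len(self.timepoints_h) * self.arrays_per_cell)


@dataclass
class EffectSpec:
    """Planted-signal specification; categories are disjoint by construction."""

    frac_treatment_de: float = 0.05
    frac_genotype_de: float = 0.02
    frac_interaction_de: float = 0.02
    frac_lab_inconsistent: float = 0.02
    log2_effect_size: float = 1.0
    frac_anchored: float = 0.05
    anchor_strength: float = 0.9
    noise_sd_log2: float = 0.25
    site_shift_log2: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_treatment_de, self.frac_genotype_de,
                 self.frac_interaction_de, self.frac_lab_inconsistent,
                 self.frac_anchored)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("planted fractions sum to more than 1")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        if not 0 <= self.anchor_strength <= 1:
            raise ValueError("anchor_strength must lie in [0, 1]")


@dataclass
class LesionKinetics:
    """Single-pulse first-order repair model of O6-mG burden.

    Units: lesions per 1e8 normal nucleotides; rates per hour.  Default
    initial burdens put the liver three orders of magnitude above brain.
    """

    initial_burden: dict = field(default_factory=lambda: {"brain": 300.0, "liver": 300000.0})
    repair_rate_per_h: dict = field(default_factory=lambda: {"wt": math.log(2) / 24.0, "ko": 0.001})
    mdq_range: tuple = (1.0, 2.6)
    measurement_cv: float = 0.2

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.repair_rate_per_h.values()):
            raise ValueError("repair rates must be non-negative")
        if any(v < 0 for v in self.initial_burden.values()):
            raise ValueError("initial burdens must be non-negative")
        if self.repair_rate_per_h["ko"] > self.repair_rate_per_h["wt"]:
            raise ValueError("knockout repair rate must not exceed wild type")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be non-negative")

    @property
    def mdq_midpoint(self) -> float:
        return 0.5 * (self.mdq_range[0] + self.mdq_range[1])


def lesion_timecourse(kinetics: LesionKinetics, genotype: str, tissue: str,
                      t_h: float, rng: np.random.Generator | None = None):
    """Observed lesion burden for one animal at time ``t_h`` post dose.

    Returns ``(value, censored)``.  The expected value decays exponentially
    from the tissue's initial burden at the genotype's repair rate; a
    lognormal measurement error with coefficient of variation
    ``measurement_cv`` is applied when an ``rng`` is given.  Observations
    below the upper end of the MDQ range are reported at the MDQ midpoint
    with the censored flag set.
    """
    if t_h < 0:
        raise ValueError("time must be non-negative")
    rate = kinetics.repair_rate_per_h[genotype]
    expected = kinetics.initial_burden[tissue] * math.exp(-rate * t_h)
    value = expected
    if rng is not None and kinetics.measurement_cv > 0:
        cv = kinetics.measurement_cv
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        # mean-preserving lognormal noise
        value = expected * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)
    if value < kinetics.mdq_range[1]:
        return kinetics.mdq_midpoint, True
    return value, False


@dataclass
class SimulatedStudy:
    """Bundle of generator outputs."""

    expression: ExpressionMatrix      # raw probe-level intensities
    sample_sheet: pd.DataFrame
    lesions: pd.DataFrame
    truth: pd.DataFrame
    annotation: pd.DataFrame

    def write(self, out_dir) -> dict:
        """Write all tables as plain text; returns {name: path}."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "expression": os.path.join(out_dir, "expression.tsv"),
            "sample_sheet": os.path.join(out_dir, "sample_sheet.csv"),
            "lesions": os.path.join(out_dir, "lesions.csv"),
            "truth": os.path.join(out_dir, "truth_labels.csv"),
            "annotation": os.path.join(out_dir, "annotation.tsv"),
        }
        self.expression.to_tsv(paths["expression"])
        self.sample_sheet.to_csv(paths["sample_sheet"], index=False)
        self.lesions.to_csv(paths["lesions"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        return paths


def _make_sample_sheet(design: StudyDesign) -> pd.DataFrame:
    rows = []
    animal = 0
    for t in design.timepoints_h:
        for site in design.sites:
            for geno in design.genotypes:
                for trt in design.treatments:
                    for rep in range(design.arrays_per_cell):
                        animal += 1
                        rows.append({
                            "sample_id": f"{site}_{geno}_{trt}_{t}h_r{rep + 1}",
                            "site": site,
                            "genotype": geno,
                            "treatment": trt,
                            "timepoint_h": t,
                            "tissue": "brain",
                            "animal_id": f"A{animal:03d}",
                        })
    return pd.DataFrame(rows)


def _make_lesion_table(sheet: pd.DataFrame, design: StudyDesign,
                       kinetics: LesionKinetics, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _, s in sheet.iterrows():
        for tissue in design.tissues:
            if s["treatment"] == "MAM":
                value, censored = lesion_timecourse(
                    kinetics, s["genotype"], tissue, float(s["timepoint_h"]), rng)
            else:
                # vehicle animals sit at the detection floor
                value, censored = kinetics.mdq_midpoint, True
            rows.append({
                "animal_id": s["animal_id"],
                "tissue": tissue,
                "timepoint_h": s["timepoint_h"],
                "lesions_per_1e8": value,
                "censored": censored,
            })
    return pd.DataFrame(rows)


def _assign_truth(design: StudyDesign, effects: EffectSpec,
                  rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_probesets
    order = rng.permutation(n)
    counts = {
        "treatment": int(round(effects.frac_treatment_de * n)),
        "genotype": int(round(effects.frac_genotype_de * n)),
        "interaction": int(round(effects.frac_interaction_de * n)),
        "lab_inconsistent": int(round(effects.frac_lab_inconsistent * n)),
        "anchored": int(round(effects.frac_anchored * n)),
    }
    rows = []
    pos = 0
    for cat in TRUTH_CATEGORIES:
        for idx in order[pos:pos + counts[cat]]:
            rows.append({"probeset_index": int(idx), "category": cat,
                         "sign": int(rng.choice([-1, 1]))})
        pos += counts[cat]
    truth = pd.DataFrame(rows, columns=["probeset_index", "category", "sign"])
    return truth


def generate_study(design: StudyDesign, effects: EffectSpec,
                   kinetics: LesionKinetics) -> SimulatedStudy:
    """Generate one complete truth-labelled study.

    Identical (design, effects, kinetics) including ``effects.seed`` give
    byte-identical outputs.
    """
    rng = np.random.default_rng(effects.seed)
    sheet = _make_sample_sheet(design)
    lesions = _make_lesion_table(sheet, design, kinetics, rng)
    truth = _assign_truth(design, effects, rng)

    n_ps = design.n_probesets
    n_arrays = len(sheet)
    ps_ids = [f"PS{i + 1:05d}_at" for i in range(n_ps)]
    gene_ids = [f"G{i + 1:05d}" for i in range(n_ps)]

    baseline = rng.normal(8.5, 1.0, size=n_ps)
    signal = np.tile(baseline[:, None], (1, n_arrays))

    is_mam = (sheet["treatment"] == "MAM").to_numpy()
    is_ko = (sheet["genotype"] == "ko").to_numpy()
    is_site2 = (sheet["site"] == design.sites[1]).to_numpy()
    e = effects.log2_effect_size

    by_cat = {c: truth[truth["category"] == c] for c in TRUTH_CATEGORIES}
    for _, r in by_cat["treatment"].iterrows():
        signal[r["probeset_index"], is_mam] += r["sign"] * e
    for _, r in by_cat["genotype"].iterrows():
        signal[r["probeset_index"], is_ko] += r["sign"] * e
    for _, r in by_cat["interaction"].iterrows():
        signal[r["probeset_index"], is_mam & is_ko] += r["sign"] * e
    for _, r in by_cat["lab_inconsistent"].iterrows():
        # site x treatment interaction: the MAM response differs between labs
        signal[r["probeset_index"], is_mam & is_site2] += r["sign"] * e

    # anchored probesets: Gaussian copula on observed brain lesion ranks so
    # anchor_strength maps onto the Spearman correlation among MAM animals
    anchored_idx = by_cat["anchored"]["probeset_index"].to_numpy()
    if anchored_idx.size:
        brain = lesions[lesions["tissue"] == "brain"].set_index("animal_id")
        rho = effects.anchor_strength
        for t in design.timepoints_h:
            cols = np.flatnonzero(is_mam & (sheet["timepoint_h"] == t).to_numpy())
            vals = brain.loc[sheet["animal_id"].iloc[cols], "lesions_per_1e8"].to_numpy()
            m = len(cols)
            ranks = stats.rankdata(vals)
            z = stats.norm.ppf((ranks - 0.375) / (m + 0.25))
            eps = rng.normal(size=(anchored_idx.size, m))
            latent = rho * z[None, :] + math.sqrt(1.0 - rho * rho) * eps
            signal[np.ix_(anchored_idx, cols)] += e * latent

    # per-site batch offset, removable by the lab term of the model
    signal[:, is_site2] += effects.site_shift_log2

    # probe-level structure: fixed additive probe affinities + iid noise
    n_probes = design.probes_per_probeset
    affinities = rng.normal(0.0, 0.5, size=(n_ps, n_probes))
    log2_probe = (np.repeat(signal, n_probes, axis=0)
                  + np.repeat(affinities.reshape(-1), n_arrays).reshape(-1, n_arrays)
                  + rng.normal(0.0, effects.noise_sd_log2, size=(n_ps * n_probes, n_arrays)))
    raw = np.exp2(log2_probe)
    raw += np.clip(rng.normal(_OPTICAL_BG_MEAN, _OPTICAL_BG_SD, size=raw.shape), 1.0, None)

    probe_ids = [f"{ps}:p{p + 1:02d}" for ps in ps_ids for p in range(n_probes)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(raw, index=pd.Index(probe_ids, name="probe_id"),
                            columns=sheet["sample_id"].tolist()),
        scale="raw")
    annotation = pd.DataFrame({
        "probe_id": probe_ids,
        "probeset_id": np.repeat(ps_ids, n_probes),
        "gene_id": np.repeat(gene_ids, n_probes),
    })
    truth_out = truth.copy()
    truth_out.insert(0, "probeset_id", [ps_ids[i] for i in truth["probeset_index"]])
    truth_out.insert(1, "gene_id", [gene_ids[i] for i in truth["probeset_index"]])
    return SimulatedStudy(expression=expr, sample_sheet=sheet, lesions=lesions,
                          truth=truth_out, annotation=annotation)


@dataclass
class StudySimulator:
    """Estimator-style front end over :func:`generate_study`."""

    design: StudyDesign = field(default_factory=StudyDesign)
    effects: EffectSpec = field(default_factory=EffectSpec)
    kinetics: LesionKinetics = field(default_factory=LesionKinetics)

    def get_params(self, deep: bool = True) -> dict:
        return {"design": self.design, "effects": self.effects, "kinetics": self.kinetics}

    def set_params(self, **params) -> "StudySimulator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def simulate(self, seed: int | None = None) -> SimulatedStudy:
        if seed is not None:
            self.effects = EffectSpec(**{**asdict(self.effects), "seed": seed})
        self.study_ = generate_study(self.design, self.effects, self.kinetics)
        return self.study_


# ---------------------------------------------------------------------------
# promoters and gene sets for the downstream regulatory stages
# ---------------------------------------------------------------------------

_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def generate_promoters(gene_ids, rng: np.random.Generator, length: int = 2000,
                       plant_motif: str | None = None, plant_frac: float = 0.0) -> dict:
    """Random upstream sequences, optionally with a motif planted.

    ``plant_frac`` of the genes (chosen at random) receive one concrete
    instantiation of the IUPAC ``plant_motif`` at a random position.
    """
    promoters = {}
    genes = list(gene_ids)
    n_plant = int(round(plant_frac * len(genes)))
    planted = set(rng.choice(len(genes), size=n_plant, replace=False)) if n_plant else set()
    bases = np.array(list("ACGT"))
    for i, g in enumerate(genes):
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        if i in planted and plant_motif:
            inst = "".join(
                _IUPAC_CHOICES[c.upper()][rng.integers(0, len(_IUPAC_CHOICES[c.upper()]))]
                for c in plant_motif)
            pos = int(rng.integers(0, length - len(inst) + 1))
            seq = seq[:pos] + inst + seq[pos + len(inst):]
        promoters[g] = seq
    return promoters


def generate_gene_sets(universe, rng: np.random.Generator, n_terms: int = 20,
                       size_range: tuple = (10, 80),
                       enriched_in=None, n_enriched_terms: int = 0,
                       enrich_frac: float = 0.5) -> dict:
    """Random GMT-style gene sets over ``universe``.

    The first ``n_enriched_terms`` terms draw ``enrich_frac`` of their
    members from ``enriched_in`` (if given), the rest uniformly.
    """
    universe = list(universe)
    enriched_in = list(enriched_in or [])
    sets = {}
    for i in range(n_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if i < n_enriched_terms and enriched_in:
            k = min(int(round(enrich_frac * size)), len(enriched_in))
            inside = list(rng.choice(enriched_in, size=k, replace=False))
            outside = [g for g in universe if g not in set(inside)]
            rest = list(rng.choice(outside, size=max(size - k, 0), replace=False))
            members = inside + rest
        else:
            members = list(rng.choice(universe, size=min(size, len(universe)),
                                      replace=False))
        sets[f"TERM{i + 1:03d}"] = sorted(members)
    return sets
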
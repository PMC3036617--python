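"""Synthetic probe-level two-species experiments with known ground truth.

The generator emulates the study system: a custom songbird oligo array
(23,136 ESTs at full scale, 11 PM probes each except a small tail with
8-10), hybridised to brain RNA of males and females of two passerine
species.  Because male birds carry two Z chromosomes and females one, and
avian dosage compensation is incomplete, a configurable fraction of Z-linked
ESTs receives a male-biased dosage effect (mean fold change ~1.2); a small
minority of autosomal ESTs is sex-biased in either direction.  The second
species is an independent hybridisation of the same array in which a
fraction of probes fails due to sequence divergence (emulating the
comparative genomic hybridisation mask) and only a configurable share of the
sex effects is shared between species.

The probe-level signal model mirrors the additive RMA model on the log2
scale::

    log2 y[p, s] = baseline[est] + effect[est] * [s is male]
                   + pop_effect[est] * [s in population 2]   (species B only)
                   + affinity[p] + eps,     eps ~ Normal(0, noise_sd)

Masked probes in species B are replaced by a depressed noisy background draw
rather than being deleted, so that the downstream mask/retention *filter* —
not the generator — is what removes them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ArrayDesign, SampleSheet

__all__ = ["SimConfig", "SimulatedExperiment", "simulate_experiment", "write_truth", "read_truth"]

_FULL_SCALE_ESTS = 23136
_FULL_SCALE_SHORT = 148
_FULL_SCALE_UNANNOT = 4107
_FULL_SCALE_PROBES = 254430
_FULL_SCALE_MASKED = 9827


@dataclass
class SimConfig:
    """Study conditions for one simulated two-species experiment.

    Defaults are anchored to the real array and study design: 4.6% of ESTs
    Z-annotated, 4,107/23,136 without annotation, 148/23,136 short probe
    sets, 9,827/254,430 probes failing cross-species hybridisation, six
    replicates per sex, and a mean male Z-dosage effect of log2(1.2).
    """

    n_ests: int = 2000
    probes_per_est: int = 11
    frac_short: float = _FULL_SCALE_SHORT / _FULL_SCALE_ESTS
    frac_z: float = 0.046
    frac_unannotated: float = _FULL_SCALE_UNANNOT / _FULL_SCALE_ESTS
    n_per_sex: int = 6
    frac_z_uncompensated: float = 0.33
    dosage_log2fc: float = float(np.log2(1.2))
    frac_autosomal_biased: float = 0.002
    autosomal_effect_log2: float = 0.6
    effect_cv: float = 0.25  # sd of an effect draw as a fraction of its mean
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    probe_affinity_sd: float = 0.7
    noise_sd: float = 0.25
    redundancy_rate: float = 0.1
    cgh_dropout_frac: float = _FULL_SCALE_MASKED / _FULL_SCALE_PROBES
    species_shared_frac: float = 0.5
    frac_population_biased: float = 0.005
    population_effect_log2: float = 0.6
    masked_background_log2: float = 4.0
    masked_background_sd: float = 0.7
    species_labels: tuple[str, str] = ("speciesA", "speciesB")
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_short": self.frac_short,
            "frac_z": self.frac_z,
            "frac_unannotated": self.frac_unannotated,
            "frac_z_uncompensated": self.frac_z_uncompensated,
            "frac_autosomal_biased": self.frac_autosomal_biased,
            "redundancy_rate": self.redundancy_rate,
            "cgh_dropout_frac": self.cgh_dropout_frac,
            "species_shared_frac": self.species_shared_frac,
            "frac_population_biased": self.frac_population_biased,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_per_sex < 2:
            raise ValueError("n_per_sex must be >= 2")
        for name in ("baseline_sd", "probe_affinity_sd", "noise_sd", "masked_background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frac_z + self.frac_unannotated > 1.0:
            raise ValueError("frac_z + frac_unannotated exceeds 1")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulatedExperiment:
    """One simulated two-species study: inputs plus the generating truth."""

    design: ArrayDesign
    samples: SampleSheet
    probes: dict[str, pd.DataFrame]  # species label -> probe intensity matrix
    cgh_mask: list[str]  # probe ids failing cross-species hybridisation
    truth: pd.DataFrame  # per-EST generating parameters
    config: SimConfig


def _draw_effect(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Positive effect magnitude around `mean` (log2 scale)."""
    e = rng.normal(mean, cv * mean)
    return float(max(e, 0.05 * mean))


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate design, sample sheet, per-species probe matrices, mask, truth.

    Deterministic for a given config (all randomness flows from
    ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_ests
    width = max(5, len(str(n)))
    est_ids = [f"EST{i:0{width}d}" for i in range(1, n + 1)]

    # --- probe counts: mostly 11, a small tail at 8-10 ------------------
    counts = np.full(n, config.probes_per_est, dtype=int)
    n_short = int(round(config.frac_short * n))
    if n_short:
        short_idx = rng.choice(n, size=n_short, replace=False)
        counts[short_idx] = rng.integers(8, 11, size=n_short)

    # --- chromosome classes ---------------------------------------------
    u = rng.random(n)
    chrom_class = np.where(
        u < config.frac_z, "Z", np.where(u < config.frac_z + config.frac_unannotated, "none", "A")
    )
    autosome_names = [f"chr{k}" for k in range(1, 29)]
    chromosome = np.empty(n, dtype=object)
    evalue = np.empty(n, dtype=float)
    for i in range(n):
        if chrom_class[i] == "Z":
            chromosome[i] = "Z"
            evalue[i] = 10.0 ** -int(rng.integers(21, 80))
        elif chrom_class[i] == "A":
            chromosome[i] = autosome_names[int(rng.integers(0, len(autosome_names)))]
            evalue[i] = 10.0 ** -int(rng.integers(21, 80))
        else:
            chromosome[i] = "none"
            # unannotated: either a weak (non-significant) hit or no hit at all
            evalue[i] = 10.0 ** -int(rng.integers(1, 20)) if rng.random() < 0.5 else np.nan

    # --- gene assignment: redundancy within a chromosome class -----------
    gene_id = np.empty(n, dtype=object)
    gene_counter = 0
    annotated_idx = [i for i in range(n) if chrom_class[i] != "none"]
    # group annotated ESTs per chromosome so gene members share a location
    by_chrom: dict[str, list[int]] = {}
    for i in annotated_idx:
        by_chrom.setdefault(chromosome[i], []).append(i)
    for members in by_chrom.values():
        order = list(rng.permutation(members))
        pos = 0
        while pos < len(order):
            remaining = len(order) - pos
            if remaining >= 2 and rng.random() < config.redundancy_rate:
                size = 3 if (remaining >= 3 and rng.random() < 0.3) else 2
            else:
                size = 1
            gene_counter += 1
            gid = f"G{gene_counter:06d}"
            for i in order[pos : pos + size]:
                gene_id[i] = gid
            pos += size
    for i in range(n):
        if chrom_class[i] == "none":
            gene_id[i] = None  # its own (non-redundant) gene

    # --- sex effects, drawn per gene so redundant ESTs agree -------------
    effect = np.zeros(n)
    direction = np.array(["none"] * n, dtype=object)
    compensated = np.array([chrom_class[i] == "Z" for i in range(n)], dtype=bool)
    in_a = np.zeros(n, dtype=bool)
    in_b = np.zeros(n, dtype=bool)

    gene_members: dict[str, list[int]] = {}
    for i in range(n):
        key = gene_id[i] if gene_id[i] is not None else est_ids[i]
        gene_members.setdefault(key, []).append(i)

    for members in gene_members.values():
        lead = members[0]
        cls = chrom_class[lead]
        eff = 0.0
        direc = "none"
        if cls == "Z":
            if rng.random() < config.frac_z_uncompensated:
                eff = _draw_effect(rng, config.dosage_log2fc, config.effect_cv)
                direc = "male"
        else:  # autosomal or unannotated
            if rng.random() < config.frac_autosomal_biased:
                eff = _draw_effect(rng, config.autosomal_effect_log2, config.effect_cv)
                direc = "male" if rng.random() < 0.5 else "female"
        if direc == "none":
            present_a = present_b = False
        elif rng.random() < config.species_shared_frac:
            present_a = present_b = True
        else:
            present_a = rng.random() < 0.5
            present_b = not present_a
        for i in members:
            effect[i] = eff
            direction[i] = direc
            in_a[i] = present_a and direc != "none"
            in_b[i] = present_b and direc != "none"
            if cls == "Z":
                compensated[i] = direc == "none"

    # population effect (species B only; independent of sex)
    pop_effect = np.zeros(n)
    for members in gene_members.values():
        if rng.random() < config.frac_population_biased:
            eff = _draw_effect(rng, config.population_effect_log2, config.effect_cv)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for i in members:
                pop_effect[i] = sign * eff

    # --- design table -----------------------------------------------------
    probe_ids: list[tuple[str, ...]] = []
    all_probes: list[str] = []
    for i, est in enumerate(est_ids):
        ps = tuple(f"{est}_p{j:02d}" for j in range(1, counts[i] + 1))
        probe_ids.append(ps)
        all_probes.extend(ps)
    design = ArrayDesign(
        pd.DataFrame(
            {
                "probe_ids": probe_ids,
                "gene_id": gene_id,
                "chromosome": chromosome,
                "evalue": evalue,
            },
            index=pd.Index(est_ids, name="est_id"),
        )
    )

    # --- samples ----------------------------------------------------------
    sp_a, sp_b = config.species_labels
    rows = []
    for sp in (sp_a, sp_b):
        tag = "A" if sp == sp_a else "B"
        for sex in ("male", "female"):
            for k in range(1, config.n_per_sex + 1):
                if sp == sp_b:
                    pop = "pop1" if k <= (config.n_per_sex + 1) // 2 else "pop2"
                else:
                    pop = "colony"
                rows.append(
                    {
                        "sample_id": f"{tag}_{sex[0]}{k:02d}",
                        "species": sp,
                        "sex": sex,
                        "population": pop,
                    }
                )
    sheet = SampleSheet(pd.DataFrame(rows).set_index("sample_id"))

    # --- CGH mask ---------------------------------------------------------
    n_masked = int(round(config.cgh_dropout_frac * len(all_probes)))
    masked = sorted(rng.choice(all_probes, size=n_masked, replace=False).tolist())
    masked_set = set(masked)

    # --- intensities ------------------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    affinity = rng.normal(0.0, config.probe_affinity_sd, size=len(all_probes))
    affinity_by_probe = dict(zip(all_probes, affinity))

    probe_est_index = np.repeat(np.arange(n), counts)  # row -> EST index

    matrices: dict[str, pd.DataFrame] = {}
    for sp, present in ((sp_a, in_a), (sp_b, in_b)):
        sp_sheet = sheet.for_species(sp)
        sample_ids = list(sp_sheet.index)
        is_male = (sp_sheet["sex"] == "male").to_numpy()
        is_pop2 = (sp_sheet["population"] == "pop2").to_numpy()
        n_probes_total = len(all_probes)
        signed = np.where(direction == "female", -effect, effect)
        est_effect = np.where(present, signed, 0.0)
        log2sig = (
            baseline[probe_est_index][:, None]
            + np.outer(est_effect[probe_est_index], is_male.astype(float))
            + np.array([affinity_by_probe[p] for p in all_probes])[:, None]
            + rng.normal(0.0, config.noise_sd, size=(n_probes_total, len(sample_ids)))
        )
        if sp == sp_b:
            log2sig += np.outer(pop_effect[probe_est_index], is_pop2.astype(float))
            mask_rows = np.array([p in masked_set for p in all_probes])
            n_mask_rows = int(mask_rows.sum())
            if n_mask_rows:
                log2sig[mask_rows, :] = rng.normal(
                    config.masked_background_log2,
                    config.masked_background_sd,
                    size=(n_mask_rows, len(sample_ids)),
                )
        matrices[sp] = pd.DataFrame(
            np.exp2(log2sig), index=pd.Index(all_probes, name="probe_id"), columns=sample_ids
        )

    truth = pd.DataFrame(
        {
            "gene_id": [gene_id[i] if gene_id[i] is not None else est_ids[i] for i in range(n)],
            "chromosome": chromosome,
            "compensated": compensated,
            "direction_a": np.where(in_a, direction, "none"),
            "effect_a": np.where(in_a, np.where(direction == "female", -effect, effect), 0.0),
            "direction_b": np.where(in_b, direction, "none"),
            "effect_b": np.where(in_b, np.where(direction == "female", -effect, effect), 0.0),
            "population_effect_b": pop_effect,
        },
        index=pd.Index(est_ids, name="est_id"),
    )

    return SimulatedExperiment(design, sheet, matrices, masked, truth, config)


def write_truth(truth: pd.DataFrame, path: str | Path, precision: int = 6) -> None:
    truth.rename_axis("est_id").to_csv(path, sep="\t", float_format=f"%.{precision}f")


def read_truth(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    return t
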
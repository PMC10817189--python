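"""Seeded generators of MPRA-like datasets with known ground truth.

Every other module is testable without external downloads because this
module emulates the statistical structure the analysis assumes: ordered
token arrangements, an additive + pairwise latent phenotype, a monotone
saturating readout, heteroskedastic noise on the log2 activity scale, and
overdispersed barcode-level counts.  Three presets mirror the shapes of
the real libraries:

``crx_nrl_like``
    1,299 length-<=4 CRX/NRL arrangements (584 exhaustive + 715 sampled
    four-site designs), pad-prefixed fixed-length encodings with a
    promoter letter, "retina-like" truth: positive additive site effects,
    negative homotypic and positive CRX-NRL heterotypic interactions.

``cdnrm_like``
    Five-site forward-only mixtures of CRX/NEUROD1/NRL/RORB/MAZ sites.

``liver_like``
    Binned encodings of variable-position sites over two background
    letters (B for the more active template, b for the less active).

The DNA (plasmid) counts follow a negative binomial and RNA counts a
Poisson with mean proportional to DNA x 2^activity — count laws chosen to
exercise the filtering and RPM paths realistically, not taken from data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpmap import GPMapParams, allowed_pairs, gauge_fix_uniform, phi_many
from .inference import MeasurementProcess, ge_predict, noise_sample
from .tfbs_library import (
    Alphabet,
    CREDesign,
    design_cdnrm_library,
    encode_binned,
    encode_fixed,
    enumerate_exhaustive,
    make_alphabet,
    sample_arrangements,
)

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "encoding_position_alphabets",
    "sample_ground_truth",
    "simulate_measurements",
    "simulate_counts",
    "make_benchmark",
]

BASAL_ID = "BASAL"

#: Structured effect sizes of the retina-like preset (log2-activity units):
#: positive additive effects scaled by affinity, negative homotypic pairs,
#: positive CRX-NRL heterotypic pairs, CRX-Rho promoter antagonism.
_AFFINITY_SCALE = {"high": 1.0, "medium": 0.7, "low": 0.4}
_RETINA_EFFECTS = {
    "additive_site": 1.0,  # x affinity scale
    "additive_promoter": {"R": 1.2, "H": 0.0, "P": 1.2},
    "homotypic": -0.8,  # x product of affinity scales
    "heterotypic_crx_nrl": 0.5,
    "crx_promoter": -0.3,
    "jitter_sd": 0.1,
}


@dataclass
class GroundTruth:
    """True parameters behind a synthetic dataset.

    ``params`` is the truth in the uniform gauge (the gauge in which fitted
    parameters are compared); ``raw_params`` keeps the as-constructed
    values whose sign pattern is guaranteed by construction.
    """

    params: GPMapParams
    raw_params: GPMapParams
    measurement: MeasurementProcess
    seed: int

    def to_json(self, path=None) -> str:
        obj = {
            "seed": self.seed,
            "params": json.loads(self.params.to_json()),
            "measurement": {
                "a": self.measurement.a,
                "b": self.measurement.b.tolist(),
                "c": self.measurement.c.tolist(),
                "d": self.measurement.d.tolist(),
                "noise_family": self.measurement.noise_family,
                "scale_coef": np.asarray(self.measurement.scale_coef).tolist(),
            },
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class SyntheticDataset:
    """Simulated library: designs, encodings, true phi / yhat, observed y."""

    seqs: list
    phi: np.ndarray
    yhat: np.ndarray
    y: np.ndarray  # (n, replicates) log2 activities
    table: pd.DataFrame
    designs: list | None = None


def encoding_position_alphabets(alphabet: Alphabet, target_len: int) -> tuple:
    """Position alphabets of fixed-length encodings: pad+site characters at
    each of the ``target_len`` site positions, promoter codes at the end."""
    site = (alphabet.pad_code,) + alphabet.site_codes
    return tuple([tuple(sorted(site))] * target_len + [tuple(alphabet.promoter_codes)])


def _near_identity_measurement(scale_coef) -> MeasurementProcess:
    # one gently saturating tanh component, approximately the identity over
    # the phi range of the presets
    return MeasurementProcess(
        a=0.0,
        b=np.array([20.0]),
        c=np.array([0.05]),
        d=np.array([0.0]),
        noise_family="gaussian",
        scale_coef=np.asarray(scale_coef, float),
    )


def sample_ground_truth(
    position_alphabets,
    architecture: str = "pairwise",
    additive_sd: float = 1.0,
    pairwise_sd: float = 0.5,
    pairwise_sparsity: float = 1.0,
    seed: int = 0,
    preset: str | None = None,
    alphabet: Alphabet | None = None,
    noise_sd: float = 0.1,
) -> GroundTruth:
    """Draw true GP-map parameters plus a measurement process.

    Random truth: additive parameters i.i.d. N(0, additive_sd); pairwise
    parameters N(0, pairwise_sd) x Bernoulli(pairwise_sparsity) (sparsity 0
    gives an additive-only truth).  ``preset="retina_like"`` instead builds
    the qualitative pattern of the fitted retinal models — positive
    additive site effects growing with affinity, negative homotypic pairs,
    positive CRX-NRL pairs — and requires ``alphabet`` for token
    identities.  The stored ``params`` are uniform-gauge fixed.
    """
    rng = np.random.default_rng(seed)
    position_alphabets = tuple(tuple(a) for a in position_alphabets)
    L = len(position_alphabets)
    pairs = allowed_pairs(L, architecture)
    theta_add, theta_pair = {}, {}
    if preset is None:
        for i, alpha in enumerate(position_alphabets):
            for ch in alpha:
                theta_add[(i, ch)] = float(rng.normal(0, additive_sd))
        for (i, j) in pairs:
            for a in position_alphabets[i]:
                for b in position_alphabets[j]:
                    v = rng.normal(0, pairwise_sd) * (rng.random() < pairwise_sparsity)
                    theta_pair[(i, j, a, b)] = float(v)
    elif preset == "retina_like":
        if alphabet is None:
            raise ValueError("retina_like preset requires the library alphabet")
        eff = _RETINA_EFFECTS
        tok = {t.code: t for t in alphabet.site_tokens}

        def site_scale(ch):
            return _AFFINITY_SCALE[tok[ch].affinity]

        for i, alpha in enumerate(position_alphabets):
            for ch in alpha:
                if ch in tok:
                    base = eff["additive_site"] * site_scale(ch)
                elif ch in alphabet.promoter_codes:
                    base = eff["additive_promoter"].get(ch, 0.0)
                else:  # pad
                    base = 0.0
                # multiplicative jitter preserves the constructed sign pattern
                jit = 1.0 + rng.normal(0, eff["jitter_sd"]) if base != 0.0 else 1.0
                theta_add[(i, ch)] = float(base * jit)
        for (i, j) in pairs:
            for a in position_alphabets[i]:
                for b in position_alphabets[j]:
                    base = 0.0
                    if a in tok and b in tok:
                        fams = {tok[a].tf, tok[b].tf}
                        scale = site_scale(a) * site_scale(b)
                        if len(fams) == 1:
                            base = eff["homotypic"] * scale
                        elif fams == {"CRX", "NRL"}:
                            base = eff["heterotypic_crx_nrl"] * scale
                    elif a in tok and tok[a].tf == "CRX" and b in ("R", "P"):
                        base = eff["crx_promoter"] * site_scale(a)
                    jit = 1.0 + rng.normal(0, eff["jitter_sd"]) if base != 0.0 else 1.0
                    theta_pair[(i, j, a, b)] = float(base * jit)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    raw = GPMapParams(position_alphabets, architecture, 0.0, theta_add, theta_pair)
    mp = _near_identity_measurement([np.log(max(noise_sd, 1e-12))])
    return GroundTruth(gauge_fix_uniform(raw), raw, mp, seed)


def simulate_measurements(
    truth: GroundTruth,
    seqs,
    replicates: int = 1,
    seed: int = 0,
    noise_sd: float | None = None,
) -> SyntheticDataset:
    """Simulate log2 activities: phi -> yhat = g(phi) -> y ~ noise(yhat).

    ``noise_sd``, if given, overrides the truth's noise scale; interpret it
    as the gaussian SD of the observed log2 activity around yhat (use
    ``0.1 * np.std(phi)`` for the benchmark noise level).  With zero noise
    y equals yhat exactly.
    """
    seqs = list(seqs)
    phi = phi_many(seqs, truth.params)
    yhat = ge_predict(phi, truth.measurement)
    mp = truth.measurement
    if noise_sd is not None:
        mp = MeasurementProcess(
            a=mp.a, b=mp.b, c=mp.c, d=mp.d,
            noise_family=mp.noise_family,
            scale_coef=np.array([np.log(max(noise_sd, 1e-12))]),
            shape_a_coef=mp.shape_a_coef, shape_b_coef=mp.shape_b_coef,
        )
    rng = np.random.default_rng(seed)
    sd = np.exp(mp.scale_coef[0])
    y = np.empty((len(seqs), replicates))
    for r in range(replicates):
        y[:, r] = yhat if sd < 1e-10 else noise_sample(rng, yhat, mp)
    cols = {"encoded_text": seqs}
    for r in range(replicates):
        cols[f"activity_rep{r + 1}"] = 2.0 ** y[:, r]
    cols["log2_activity"] = y.mean(axis=1)
    table = pd.DataFrame(cols)
    return SyntheticDataset(seqs, phi, yhat, y, table)


def simulate_counts(
    dataset: SyntheticDataset,
    barcodes_per_cre: int = 3,
    depth: float = 675.0,
    dispersion: float = 10.0,
    seed: int = 0,
    basal_barcodes: int = 90,
) -> pd.DataFrame:
    """Barcode-level RNA/DNA count table for a simulated dataset.

    DNA reads per barcode follow a negative binomial around ``depth``
    (gamma-Poisson with shape ``dispersion``); RNA reads are Poisson with
    mean proportional to DNA x 2^activity, so RPM ratios recover the
    activity.  The basal construct (cre_id ``BASAL``, activity 1) is
    included with ``basal_barcodes`` barcodes per replicate.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    n, reps = dataset.y.shape
    cre_ids = [f"cre{i:05d}" for i in range(n)]
    rows = []
    for rep in range(1, reps + 1):
        ids = cre_ids + [BASAL_ID]
        ratios = np.concatenate([2.0 ** dataset.y[:, rep - 1], [1.0]])
        n_bc = [barcodes_per_cre] * n + [basal_barcodes]
        for cid, ratio, nb in zip(ids, ratios, n_bc):
            p = dispersion / (dispersion + depth)
            dna = rng.negative_binomial(dispersion, p, size=nb)
            rna = rng.poisson(dna * ratio)
            for k in range(nb):
                rows.append(
                    {
                        "barcode": f"{cid}_bc{k}_r{rep}",
                        "cre_id": cid,
                        "replicate": rep,
                        "rna_reads": int(rna[k]),
                        "dna_reads": int(dna[k]),
                    }
                )
    return pd.DataFrame(rows)


def make_benchmark(preset: str, seed: int = 0, out_dir=None, **kwargs):
    """One call emits a complete synthetic fixture: designs, encodings,
    ground truth, activities (and counts on request via simulate_counts).

    Returns ``(SyntheticDataset, GroundTruth)``.  Presets fix the library
    shapes to those of the corresponding real libraries.
    """
    rng = np.random.default_rng(seed)
    if preset == "crx_nrl_like":
        alphabet = make_alphabet("crx_nrl")
        designs = enumerate_exhaustive(alphabet.site_codes, 1, 3)
        designs += sample_arrangements(alphabet.site_codes, 4, 715, seed=seed + 1)
        promoters = rng.choice(["R", "H"], size=len(designs))
        designs = [
            CREDesign(d.sites, pr, d.token_string + pr)
            for d, pr in zip(designs, promoters)
        ]
        seqs = [encode_fixed(d, 4, alphabet) for d in designs]
        truth = sample_ground_truth(
            encoding_position_alphabets(alphabet, 4),
            "pairwise",
            preset="retina_like",
            alphabet=alphabet,
            seed=seed + 2,
        )
    elif preset == "cdnrm_like":
        alphabet = make_alphabet("cdnrm")
        designs = design_cdnrm_library(alphabet)
        n_sub = kwargs.get("n_designs")
        if n_sub is not None and n_sub < len(designs):
            idx = rng.choice(len(designs), size=n_sub, replace=False)
            designs = [designs[i] for i in sorted(idx)]
        seqs = [encode_fixed(d, 5, alphabet) for d in designs]
        truth = sample_ground_truth(
            encoding_position_alphabets(alphabet, 5),
            "pairwise",
            preset="retina_like",
            alphabet=alphabet,
            seed=seed + 2,
        )
    elif preset == "liver_like":
        n = kwargs.get("n_designs", 500)
        tf_codes = list("ABCDEFGHIJKL")  # twelve liver TF token letters
        n_bins, bin_size = 13, 9
        seqs = []
        for _ in range(n):
            background = rng.choice(["B", "b"])
            sites = []
            n_sites = rng.integers(1, 9)
            bins = rng.choice(n_bins, size=n_sites, replace=False)
            for bn in bins:
                sites.append((int(bn) * bin_size + int(rng.integers(0, bin_size)),
                              str(rng.choice(tf_codes))))
            seqs.append(
                encode_binned(n_bins * bin_size, sites, bin_size, background)
            )
        designs = None
        position_alphabets = tuple(
            tuple(sorted(set(tf_codes + ["B", "b"]))) for _ in range(n_bins)
        )
        truth = sample_ground_truth(
            position_alphabets,
            "pairwise",
            additive_sd=0.5,
            pairwise_sd=0.2,
            pairwise_sparsity=0.2,
            seed=seed + 2,
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")

    phi = phi_many(seqs, truth.params)
    noise_sd = kwargs.get("noise_sd", 0.1 * float(np.std(phi)))
    replicates = kwargs.get("replicates", 1)
    data = simulate_measurements(truth, seqs, replicates, seed=seed + 3, noise_sd=noise_sd)
    data.designs = designs
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data.table.to_csv(out / f"{preset}_activity.tsv", sep="\t", index=False)
        truth.to_json(out / f"{preset}_truth.json")
        if designs is not None:
            pd.DataFrame(
                {
                    "design_id": [d.design_id for d in designs],
                    "token_string": [d.token_string for d in designs],
                    "promoter": [d.promoter for d in designs],
                    "encoded_text": seqs,
                }
            ).to_csv(out / f"{preset}_designs.tsv", sep="\t", index=False)
    return data, truth
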
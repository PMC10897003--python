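"""Synthetic stand-ins for the study's MRI-derived inputs.

Every generator is a pure function of (parameters, seed) and writes/returns
the same structures the real-data loaders produce, so the full analysis runs
offline:

* :func:`synth_connectome` -- a distance-dependent, symmetric, max-normalized
  structural connectome on a spherical cortical layout plus fiber lengths;
* :func:`synth_partition` -- a seven-network functional parcellation with
  realistic size imbalance;
* :func:`synth_bold_groups` -- two-group regional BOLD with an imposed global
  connectivity (GBC) reduction and synchrony reduction in the patient group,
  built from a shared narrowband (0.04-0.07 Hz) latent drive mixed into
  region-specific narrowband noise;
* :func:`synth_motion_table` -- framewise-displacement summaries for the
  motion-threshold sensitivity re-analysis.

The latent-drive construction is deliberately independent of the network
simulator so the empirical-arm pipeline (metrics -> stats) is tested without
circularity; the simulator provides a second, model-based fixture path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .connectome import build_connectome
from .network import Connectome
from .metrics import Partition, YEO7, bandpass

__all__ = [
    "synth_connectome",
    "synth_average_connectome",
    "synth_partition",
    "synth_bold_groups",
    "synth_motion_table",
    "apply_motion_threshold",
]


def synth_connectome(n_regions: int = 80, seed: int = 0,
                     density: float = 0.3, length_scale_mm: float = 35.0,
                     radius_mm: float = 70.0, jitter_sd: float = 0.8,
                     v_gl_m_per_s: float = 20.0):
    """Distance-dependent synthetic connectome.

    Regions are placed uniformly on a sphere of cortical scale; weights decay
    exponentially with Euclidean distance, carry multiplicative lognormal
    jitter, and are thresholded to the requested edge density before
    symmetrization and max-normalization.  Fiber lengths are the Euclidean
    distances.  Returns (Connectome, lengths_mm).

    The defaults reproduce the salient statistics of max-normalized
    probabilistic-tractography matrices: heavy-tailed weights (lognormal
    jitter, ~30-fold distance attenuation across the brain) and total
    normalized input per region near 2, which places the default network
    model on the rising branch of the coupling-connectivity relationship --
    the regime in which the whole-brain analysis operates.
    """
    rng = np.random.default_rng(seed)
    xyz = rng.standard_normal((n_regions, 3))
    xyz *= radius_mm / np.linalg.norm(xyz, axis=1, keepdims=True)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    jitter = np.exp(jitter_sd * rng.standard_normal((n_regions, n_regions))) \
        if jitter_sd > 0 else np.ones((n_regions, n_regions))
    W = np.exp(-dist / length_scale_mm) * jitter
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)
    if density < 1.0:
        off = W[np.triu_indices(n_regions, k=1)]
        thr = np.quantile(off, 1.0 - density)
        W[W < thr] = 0.0
    con = build_connectome(W, dist, v_gl_m_per_s=v_gl_m_per_s)
    return con, dist


def synth_average_connectome(n_regions: int = 80, seed: int = 0,
                             n_subjects: int = 43, density: float = 0.3,
                             length_scale_mm: float = 15.0,
                             radius_mm: float = 70.0, jitter_sd: float = 0.8,
                             v_gl_m_per_s: float = 20.0,
                             layout_seed: int = 7):
    """Group-average synthetic connectome on a fixed atlas layout.

    Emulates the study design of averaging max-normalized individual
    connectomes: one shared spatial layout (the regions are an atlas, fixed
    across subjects and studies via ``layout_seed``), per-subject lognormal
    weight jitter seeded from ``seed``, mean of the normalized matrices
    re-normalized to unit maximum.  Averaging removes the
    realization-to-realization variance of total coupling that a single
    jittered matrix carries; with the default kernel the average substrate
    delivers a total relative input per region near 2, the scale at which
    the network model operates on the rising branch of the
    coupling-connectivity relationship.  Returns (Connectome, lengths_mm).
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    base, dist = synth_connectome(
        n_regions, seed=layout_seed, density=density,
        length_scale_mm=length_scale_mm, radius_mm=radius_mm,
        jitter_sd=0.0, v_gl_m_per_s=v_gl_m_per_s)
    mats = []
    for s in sub_seeds:
        # same layout for every subject; only the weight jitter varies
        jit = np.exp(jitter_sd * np.random.default_rng(int(s))
                     .standard_normal((n_regions, n_regions)))
        mats.append(base.C * 0.5 * (jit + jit.T))
    from .connectome import average_connectomes, delays_from_lengths
    C = average_connectomes(mats)
    con = Connectome(C=C, D=delays_from_lengths(dist, v_gl_m_per_s))
    con.validate()
    return con, dist


def synth_partition(n_regions: int = 80, seed: int = 0) -> Partition:
    """Seven-network partition with realistic size imbalance."""
    rng = np.random.default_rng(seed)
    # relative network sizes loosely follow cortical surface shares
    props = np.array([0.18, 0.16, 0.20, 0.12, 0.10, 0.08, 0.16])
    sizes = np.maximum(np.round(props * n_regions).astype(int), 1)
    while sizes.sum() > n_regions:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_regions:
        sizes[np.argmin(sizes)] += 1
    labels = np.repeat(np.asarray(YEO7, dtype=object), sizes)
    rng.shuffle(labels)
    return Partition(labels=list(labels))


def _narrowband(rng, n_series: int, T_volumes: int, TR_s: float):
    """Unit-variance narrowband (0.04-0.07 Hz) Gaussian series."""
    import warnings
    white = rng.standard_normal((n_series, T_volumes))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nb = bandpass(white, TR_s)
    sd = nb.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return nb / sd


def synth_bold_groups(n_controls: int = 43, n_patients: int = 38,
                      n_regions: int = 80, T_volumes: int = 150,
                      TR: float = 2.0, gbc_effect: float = 0.11,
                      sync_effect: float = 0.12, seed: int = 0,
                      control_gbc: float = 0.35, gbc_subject_sd: float = 0.17,
                      phase_jitter_control: float = 0.25,
                      sync_gain: float = 2.0):
    """Two-group regional BOLD with imposed GBC and synchrony reductions.

    Each subject's regional series is ``lam * z_k + sqrt(1-lam^2) * eps_k``
    where z_k is a shared narrowband drive with a static per-region phase
    offset (SD ``phase_jitter`` rad) and eps_k is independent narrowband
    noise.  The mixing coefficient is calibrated per subject so the expected
    off-diagonal correlation equals a GBC target drawn around the group mean
    (patients: ``control_gbc - gbc_effect``); patients additionally receive
    larger phase jitter (``sync_gain * sync_effect`` extra SD), reducing the
    Kuramoto order parameter by approximately ``sync_effect``.

    Returns (controls, patients, records): two lists of (n_regions, T) arrays
    and a DataFrame with each subject's group, seed and imposed parameters.
    """
    rng = np.random.default_rng(seed)
    groups = [("control", n_controls, control_gbc, phase_jitter_control),
              ("patient", n_patients, control_gbc - gbc_effect,
               phase_jitter_control + sync_gain * sync_effect)]
    out = {"control": [], "patient": []}
    records = []
    for gname, n_sub, gbc_mean, jitter in groups:
        for s in range(n_sub):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            target = float(np.clip(sub_rng.normal(gbc_mean, gbc_subject_sd),
                                   0.02, 1.0))
            # compensate the de-correlating effect of the phase jitter:
            # E[corr] = lam^2 * exp(-jitter^2)
            lam = float(np.sqrt(min(target / np.exp(-jitter ** 2), 1.0)))
            z = _narrowband(sub_rng, 1, T_volumes, TR)[0]
            z_an = hilbert(z)
            theta = sub_rng.normal(0.0, jitter, n_regions)
            z_k = np.real(z_an[None, :] * np.exp(1j * theta)[:, None])
            zsd = z_k.std(axis=1, keepdims=True)
            zsd[zsd == 0] = 1.0
            z_k = z_k / zsd
            eps = _narrowband(sub_rng, n_regions, T_volumes, TR)
            bold = lam * z_k + np.sqrt(1.0 - lam ** 2) * eps
            out[gname].append(bold)
            records.append({"group": gname, "subject": len(out[gname]) - 1,
                            "seed": sub_seed, "target_gbc": target,
                            "lambda": lam, "phase_jitter": jitter})
    return out["control"], out["patient"], pd.DataFrame(records)


def synth_motion_table(n_subjects: int = 81, seed: int = 0,
                       group_shift: float = 0.05,
                       n_controls: int | None = None) -> pd.DataFrame:
    """Relative mean framewise displacement (mm RMS) for two groups.

    Controls are lognormal around ~0.15 mm; patients are shifted upward by
    ``group_shift``, mirroring the higher in-scanner motion of the patient
    group.
    """
    rng = np.random.default_rng(seed)
    n_controls = n_subjects // 2 if n_controls is None else n_controls
    n_patients = n_subjects - n_controls
    fd_c = np.exp(rng.normal(np.log(0.13), 0.45, n_controls))
    fd_p = np.exp(rng.normal(np.log(0.13), 0.45, n_patients)) + group_shift
    return pd.DataFrame({
        "subject": range(n_subjects),
        "group": ["control"] * n_controls + ["patient"] * n_patients,
        "fd_rms": np.concatenate([fd_c, fd_p]),
    })


def apply_motion_threshold(table: pd.DataFrame, threshold: float = 0.3):
    """Exclude subjects whose framewise displacement exceeds the threshold.

    Returns (kept_table, excluded_table).  Refuses (ValueError) when a group
    would be left with fewer than two subjects, since no group statistic can
    be formed downstream.
    """
    keep = table[table["fd_rms"] <= threshold]
    drop = table[table["fd_rms"] > threshold]
    counts = keep.groupby("group").size() if len(keep) else pd.Series(dtype=int)
    for g in table["group"].unique():
        if counts.get(g, 0) < 2:
            raise ValueError(
                f"motion threshold {threshold} leaves group '{g}' with "
                f"{counts.get(g, 0)} subjects; group statistics are undefined")
    return keep.reset_index(drop=True), drop.reset_index(drop=True)
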
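"""Connectivity and temporal-dynamics measures for regional BOLD tables.

Implements the analysis battery applied identically to empirical and
simulated regions x time BOLD data:

* functional connectivity (FC): pairwise Pearson correlation over the whole
  acquisition;
* global brain connectivity (GBC): a region's mean correlation to the other
  regions, averaged globally, per functional network, and over
  association/sensory super-groups;
* synchrony and metastability: mean and standard deviation of the Kuramoto
  order parameter R(t) computed from the instantaneous (Hilbert) phases of
  the 0.04-0.07 Hz narrowband signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Partition",
    "MetricsReport",
    "functional_connectivity",
    "gbc",
    "subnetwork_gbc",
    "bandpass",
    "kuramoto",
    "metrics_report",
]

YEO7 = ("SomMot", "Cont", "Def", "Sal/VAttn", "DAttn", "Lim", "Vis")
ASSOCIATION = ("Def", "Cont", "Sal/VAttn")
SENSORY = ("SomMot", "Vis", "DAttn")


@dataclass
class Partition:
    """Region-to-functional-network assignment over the seven networks.

    Association areas comprise the default-mode, control and salience/ventral
    attention networks; sensory areas the somato-motor, visual and dorsal
    attention networks; the limbic network belongs to neither super-group.
    """

    labels: list  # one network name per region

    def __post_init__(self):
        bad = set(self.labels) - set(YEO7)
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def mask(self, network: str) -> np.ndarray:
        return np.asarray([l == network for l in self.labels])

    @property
    def association_mask(self) -> np.ndarray:
        return np.asarray([l in ASSOCIATION for l in self.labels])

    @property
    def sensory_mask(self) -> np.ndarray:
        return np.asarray([l in SENSORY for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region": range(self.n), "network": self.labels})

    @classmethod
    def from_file(cls, path) -> "Partition":
        df = pd.read_csv(path, sep="\t")
        return cls(labels=list(df["network"]))

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class MetricsReport:
    """Connectivity/dynamics summary for one (real or virtual) subject."""

    FC: np.ndarray
    gbc_region: np.ndarray
    gbc_global: float
    gbc_per_network: dict
    gbc_association: float
    gbc_sensory: float
    mean_R: float
    metastability: float
    extras: dict = field(default_factory=dict)

    def flat(self) -> dict:
        rec = {"gbc_global": self.gbc_global,
               "gbc_association": self.gbc_association,
               "gbc_sensory": self.gbc_sensory,
               "mean_R": self.mean_R,
               "metastability": self.metastability}
        rec.update({f"gbc_{k}": v for k, v in self.gbc_per_network.items()})
        return rec


def functional_connectivity(bold: np.ndarray) -> np.ndarray:
    """Pearson-correlation FC matrix of a regions x time table."""
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[1] < 3:
        raise ValueError("need a 2-D table with at least 3 time points")
    sd = bold.std(axis=1)
    const = sd <= 1e-12 * (1.0 + np.abs(bold.mean(axis=1)))
    if np.any(const):
        bad = int(np.argmax(const))
        raise ValueError(f"constant BOLD series in region {bad}")
    return np.corrcoef(bold)


def gbc(FC: np.ndarray, include_self: bool = False):
    """Region-wise and global GBC.

    By default the self-correlation is excluded and the sum divided by n-1,
    following the GBC literature; ``include_self=True`` averages the full row
    over n instead (an affine shift that leaves group contrasts unchanged).
    """
    FC = np.asarray(FC, dtype=float)
    n = FC.shape[0]
    if include_self:
        region = FC.sum(axis=1) / n
    else:
        region = (FC.sum(axis=1) - np.diag(FC)) / (n - 1)
    return region, float(region.mean())


def subnetwork_gbc(gbc_region: np.ndarray, partition: Partition):
    """Mean regional GBC per network and for the two super-groups."""
    gbc_region = np.asarray(gbc_region, dtype=float)
    if gbc_region.shape[0] != partition.n:
        raise ValueError("partition size does not match GBC vector")
    per_network = {}
    for net in YEO7:
        m = partition.mask(net)
        per_network[net] = float(gbc_region[m].mean()) if m.any() else np.nan
    am, sm = partition.association_mask, partition.sensory_mask
    assoc = float(gbc_region[am].mean()) if am.any() else float("nan")
    sens = float(gbc_region[sm].mean()) if sm.any() else float("nan")
    return per_network, assoc, sens


def bandpass(bold: np.ndarray, TR_s: float, low: float = 0.04,
             high: float = 0.07, order: int = 2) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass with reflective padding."""
    bold = np.asarray(bold, dtype=float)
    fs = 1.0 / TR_s
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz at/above Nyquist {nyq} Hz")
    b, a = sps.butter(order, [low / nyq, high / nyq], btype="band")
    padlen = min(3 * max(len(a), len(b)), bold.shape[-1] - 1)
    n_cycles = bold.shape[-1] * TR_s * 0.5 * (low + high)
    if n_cycles < 5:
        warnings.warn(
            f"series covers only {n_cycles:.1f} passband cycles (< 5); "
            "phase-based measures will be edge-dominated", stacklevel=2)
    return sps.filtfilt(b, a, bold, axis=-1, padtype="even", padlen=padlen)


def kuramoto(filtered_bold: np.ndarray):
    """Kuramoto order parameter from analytic-signal phases.

    Returns (R_t, mean_R, metastability) where R(t) = |mean_k exp(i phi_k)|,
    synchrony is the time average of R and metastability its standard
    deviation.
    """
    x = np.asarray(filtered_bold, dtype=float)
    phases = np.angle(sps.hilbert(x, axis=-1))
    R_t = np.abs(np.exp(1j * phases).mean(axis=0))
    return R_t, float(R_t.mean()), float(R_t.std())


def metrics_report(bold, TR_s: float, partition: Partition,
                   include_self: bool = False) -> MetricsReport:
    """Full per-subject measurement battery on a regions x time BOLD table."""
    data = bold.data if hasattr(bold, "data") else np.asarray(bold)
    TR = bold.TR if hasattr(bold, "TR") else TR_s
    FC = functional_connectivity(data)
    region, glob = gbc(FC, include_self=include_self)
    per_net, assoc, sens = subnetwork_gbc(region, partition)
    filt = bandpass(data, TR)
    _, mean_R, meta = kuramoto(filt)
    return MetricsReport(FC=FC, gbc_region=region, gbc_global=glob,
                         gbc_per_network=per_net, gbc_association=assoc,
                         gbc_sensory=sens, mean_R=mean_R, metastability=meta)
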
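"""Activity-record curation and labelled data-set construction.

Raw literature records (one activity value per molecule per source) are
collapsed into one value per molecule: multiple reports are averaged,
and molecules whose reported values disagree by more than a discrepancy
limit are excluded.  Curated values are then thresholded into binary
endpoint labels (+1/-1) and class-balanced by seeded down-sampling.

Endpoint conventions (thresholds configurable, these are the defaults):

====================  =====================  ==========
endpoint              value                  positive if
====================  =====================  ==========
bioavailability       %F in [0, 100]         value >= 80
hia                   %FA in [0, 100]        value >= 70
caco2                 logPapp (unbounded)    value <= -4
====================  =====================  ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix

__all__ = [
    "ActivityRecord",
    "LabelledDataset",
    "ENDPOINTS",
    "DISCREPANCY_LIMITS",
    "curate_records",
    "assign_labels",
    "attach_labels",
    "balance_dataset",
]

#: endpoint -> (threshold, direction); direction "ge" means value >= threshold
#: is the positive class, "le" means value <= threshold.
ENDPOINTS: dict[str, tuple[float, str]] = {
    "bioavailability": (80.0, "ge"),
    "hia": (70.0, "ge"),
    "caco2": (-4.0, "le"),
}

#: default "large discrepancy" limits per endpoint (percentage points for
#: the two absorption endpoints, log units for permeability)
DISCREPANCY_LIMITS: dict[str, float] = {
    "bioavailability": 20.0,
    "hia": 20.0,
    "caco2": 1.0,
}


@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    smiles: str
    endpoint: str
    value: float
    source: str = ""

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.endpoint in ("bioavailability", "hia") and not (
            0.0 <= self.value <= 100.0
        ):
            raise ValueError(
                f"{self.endpoint} value {self.value} outside [0, 100] "
                f"for molecule {self.molecule_id}"
            )


@dataclass
class LabelledDataset:
    """Descriptor matrix rows aligned 1:1 with binary endpoint labels."""

    X: pd.DataFrame
    y: np.ndarray  # +1 / -1
    endpoint: str
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("labels must align 1:1 with matrix rows")
        if set(np.unique(self.y)) != {-1, 1}:
            raise ValueError("labels must be +1/-1 with both classes present")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> tuple[int, int]:
        return int((self.y == 1).sum()), int((self.y == -1).sum())

    def subset_descriptors(self, names) -> "LabelledDataset":
        return LabelledDataset(self.X[list(names)].copy(), self.y.copy(),
                               self.endpoint, list(self.provenance))


def curate_records(
    records: list[ActivityRecord],
    discrepancy_limit: float | None = None,
) -> tuple[list[ActivityRecord], list[dict]]:
    """Collapse multi-report molecules to their mean activity value.

    Molecules whose reported values span a range larger than
    ``discrepancy_limit`` (endpoint default if None) are excluded.
    Returns the curated records and a provenance log of what happened.
    Curation is idempotent: curated records pass through unchanged.
    """
    if not records:
        raise ValueError("no records to curate")
    log: list[dict] = []
    out: list[ActivityRecord] = []
    frame = pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in records],
            "endpoint": [r.endpoint for r in records],
            "idx": range(len(records)),
        }
    )
    for (mol_id, endpoint), group in frame.groupby(
        ["molecule_id", "endpoint"], sort=False
    ):
        grp = [records[i] for i in group["idx"]]
        limit = (discrepancy_limit if discrepancy_limit is not None
                 else DISCREPANCY_LIMITS[endpoint])
        values = [r.value for r in grp]
        if len(grp) == 1:
            out.append(grp[0])
            continue
        spread = max(values) - min(values)
        if spread > limit:
            log.append({"molecule_id": mol_id, "endpoint": endpoint,
                        "action": "excluded",
                        "reason": f"discrepancy {spread:g} > limit {limit:g}",
                        "values": values})
            continue
        mean_value = float(np.mean(values))
        log.append({"molecule_id": mol_id, "endpoint": endpoint,
                    "action": "averaged", "values": values,
                    "value": mean_value})
        out.append(replace(grp[0], value=mean_value,
                           source=";".join(sorted({r.source for r in grp}))))
    if not out:
        raise ValueError("curation excluded every molecule")
    return out, log


def assign_labels(
    records: list[ActivityRecord],
    endpoint: str,
    threshold: float | None = None,
    direction: str | None = None,
) -> pd.Series:
    """Threshold curated activity values into +1/-1 labels.

    The boundary value itself is on the positive side (>= for the
    absorption endpoints, <= for permeability), matching the stated
    class conventions.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    default_thr, default_dir = ENDPOINTS[endpoint]
    thr = default_thr if threshold is None else threshold
    sense = default_dir if direction is None else direction
    if sense not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    labels = {}
    for r in records:
        if r.endpoint != endpoint:
            continue
        positive = r.value >= thr if sense == "ge" else r.value <= thr
        labels[r.molecule_id] = 1 if positive else -1
    if not labels:
        raise ValueError(f"no records for endpoint {endpoint!r}")
    return pd.Series(labels, name=endpoint, dtype=int)


def attach_labels(matrix: DescriptorMatrix | pd.DataFrame,
                  labels: pd.Series, endpoint: str) -> LabelledDataset:
    """Join a descriptor matrix with a label series on molecule id."""
    values = matrix.values if isinstance(matrix, DescriptorMatrix) else matrix
    common = [i for i in values.index if i in labels.index]
    if not common:
        raise ValueError("no overlap between matrix rows and labels")
    x = values.loc[common]
    y = labels.loc[common].to_numpy()
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise ValueError("both classes must be non-empty")
    return LabelledDataset(x, y, endpoint)


def balance_dataset(d: LabelledDataset, seed: int) -> LabelledDataset:
    """Down-sample the majority class to a 1:1 ratio, seeded.

    Sampling is uniform without replacement; the minority class is kept
    intact.  An already balanced data set is returned with identical
    membership (rows reindexed in stable original order).
    """
    pos, neg = d.class_counts()
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be non-empty to balance")
    rng = np.random.default_rng(seed)
    idx = np.arange(d.n)
    pos_idx, neg_idx = idx[d.y == 1], idx[d.y == -1]
    if pos == neg:
        keep = idx
    else:
        major, minor = (pos_idx, neg_idx) if pos > neg else (neg_idx, pos_idx)
        sampled = rng.choice(major, size=minor.size, replace=False)
        keep = np.sort(np.concatenate([minor, sampled]))
    prov = list(d.provenance) + [{
        "action": "balanced", "seed": seed,
        "kept": int(keep.size), "dropped": int(d.n - keep.size),
    }]
    return LabelledDataset(d.X.iloc[keep].copy(), d.y[keep], d.endpoint, prov)
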
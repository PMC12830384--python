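"""Recovery metrics against ground truth.

The headline quantities are the recovered component count ``N_m`` versus
the true count ``N_e``, and the mean / standard deviation (``M_d`` /
``M_s``) of center-to-center distances between matched true and recovered
components, normalized by the diagonal of the bounding box of the input
model. Correspondence is an optimal one-to-one assignment on center
distances (Hungarian algorithm); unmatched surplus on either side is
reported but excluded from the distance statistics. ``M_s`` uses the
sample (n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["EvaluationReport", "match_components", "evaluate", "format_table"]


def _centers(obj) -> np.ndarray:
    if hasattr(obj, "centers"):  # GroundTruthAggregate
        return np.asarray(obj.centers, dtype=np.float64)
    if isinstance(obj, (list, tuple)) and obj and hasattr(obj[0], "center"):
        return np.array([np.asarray(c.center, dtype=np.float64) for c in obj])
    arr = np.asarray(obj, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of centers")
    return arr


def _truth_radii(obj) -> np.ndarray | None:
    """Per-component bounding radii when the truth object carries them."""
    comps = getattr(obj, "components", None)
    if comps is None:
        return None
    try:
        return np.array([float(np.max(c.radii)) for c in comps])
    except AttributeError:
        return None


@dataclass
class EvaluationReport:
    n_true: int
    n_found: int
    mean_center_distance: float  # M_d, normalized
    sd_center_distance: float  # M_s, normalized
    matched_pairs: list
    unmatched_truth: list
    unmatched_found: list
    distances: np.ndarray  # normalized, aligned with matched_pairs

    def to_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_found": self.n_found,
            "mean_center_distance": self.mean_center_distance,
            "sd_center_distance": self.sd_center_distance,
            "matched_pairs": [list(p) for p in self.matched_pairs],
            "unmatched_truth": list(self.unmatched_truth),
            "unmatched_found": list(self.unmatched_found),
            "distances": [float(d) for d in self.distances],
        }


def match_components(truth, found) -> list[tuple[int, int]]:
    """Minimum-total-distance one-to-one matching of true and found centers."""
    t = _centers(truth)
    f = _centers(found)
    if len(t) == 0 or len(f) == 0:
        raise ValueError("both center sets must be non-empty")
    cost = cdist(t, f)
    rows, cols = linear_sum_assignment(cost)
    return sorted(zip(rows.tolist(), cols.tolist()))


def evaluate(truth, found, cloud_bbox_diagonal: float) -> EvaluationReport:
    """Compute N_e, N_m, M_d, M_s for a truth/found pair.

    ``cloud_bbox_diagonal`` is the diagonal length of the bounding box of
    the input model (pre-normalization frame); both center sets must be
    expressed in that same frame.

    The assignment is global, but a pair only counts as a *correspondence*
    when the found center lies within the true component's bounding radius
    (available when ``truth`` is a ground-truth aggregate): a recovered
    component corresponds to the berry its center sits in. Remoter pairs —
    which a visual correspondence check would never accept — are moved to
    the unmatched lists instead of polluting the distance statistics.
    """
    if cloud_bbox_diagonal <= 0:
        raise ValueError("cloud_bbox_diagonal must be positive")
    t = _centers(truth)
    f = _centers(found)
    pairs = match_components(t, f)
    gates = _truth_radii(truth)
    if gates is not None:
        pairs = [
            (i, j) for i, j in pairs if np.linalg.norm(t[i] - f[j]) < gates[i]
        ]
        if not pairs:
            raise ValueError("no found component lies within any true component")
    dists = np.array([np.linalg.norm(t[i] - f[j]) for i, j in pairs]) / cloud_bbox_diagonal
    matched_t = {i for i, _ in pairs}
    matched_f = {j for _, j in pairs}
    m_d = float(dists.mean())
    m_s = float(dists.std(ddof=1)) if len(dists) > 1 else 0.0
    return EvaluationReport(
        n_true=len(t),
        n_found=len(f),
        mean_center_distance=m_d,
        sd_center_distance=m_s,
        matched_pairs=pairs,
        unmatched_truth=[i for i in range(len(t)) if i not in matched_t],
        unmatched_found=[j for j in range(len(f)) if j not in matched_f],
        distances=dists,
    )


def format_table(
    report: EvaluationReport,
    n_vertices: int | None = None,
    n_initial: int | None = None,
) -> str:
    """Human-readable summary mirroring the N_v / N_i / N_e / N_m / M_d / M_s columns."""
    rows = []
    if n_vertices is not None:
        rows.append(("N_v (input points)", f"{n_vertices}"))
    if n_initial is not None:
        rows.append(("N_i (initial clusters)", f"{n_initial}"))
    rows.append(("N_e (true components)", f"{report.n_true}"))
    rows.append(("N_m (found components)", f"{report.n_found}"))
    rows.append(("M_d (mean center dist., normalized)", f"{report.mean_center_distance:.6f}"))
    rows.append(("M_s (sd center dist., normalized)", f"{report.sd_center_distance:.6f}"))
    width = max(len(r[0]) for r in rows)
    return "\n".join(f"{name:<{width}}  {value}" for name, value in rows)
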
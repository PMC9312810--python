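"""Contact-ratio phi-values.

phi for a mutant is the ratio of the mutation's effect on the
transition-state ensemble to its effect on the folded state, measured in
mean native contacts:

    phi = (<Q>_TS,mut - <Q>_TS,wt) / (<Q>_F,mut - <Q>_F,wt)

phi ~ 1 means the mutated site is as structured in the transition state
as in the folded state (part of the folding nucleus); phi ~ 0 means it is
unfolded at the transition state. A denominator below ``eps`` contacts
(default 0.5 -- under the resolution of a single contact) flags the value
as undefined rather than raising, so batch runs always complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactDefinition

__all__ = ["PhiResult", "ensemble_mean_contacts", "phi", "phi_batch"]


@dataclass
class PhiResult:
    mutant_id: str
    mean_TS_mut: float
    mean_TS_wt: float
    mean_F_mut: float
    mean_F_wt: float
    numerator: float
    denominator: float
    phi: float                 # NaN when undefined
    undefined: bool
    out_of_range: bool         # phi outside [0, 1]; reported, never clipped
    n_frames: dict


def _ensemble_counts(frames: np.ndarray, native_pairs: np.ndarray,
                     cutoff: float) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("ensemble must be a nonempty (frames, atoms, 3) array")
    d = np.linalg.norm(frames[:, native_pairs[:, 0], :] -
                       frames[:, native_pairs[:, 1], :], axis=2)
    return (d <= cutoff).sum(axis=1)


def ensemble_mean_contacts(frames: np.ndarray, native_set: np.ndarray,
                           definition: ContactDefinition = ContactDefinition(),
                           residues=None) -> float:
    """Mean per-frame native-contact count over a frame ensemble.

    ``frames`` holds Calpha coordinates, (n_frames, n_residues, 3);
    ``native_set`` is the (P, 2) wild-type native pair list. ``residues``
    optionally restricts the count to contacts involving the given
    residue indices (the residue-local phi variant; default: all native
    contacts, the global form).
    """
    native_set = np.asarray(native_set, dtype=int)
    if residues is not None:
        residues = np.atleast_1d(np.asarray(residues, dtype=int))
        keep = np.isin(native_set[:, 0], residues) | \
            np.isin(native_set[:, 1], residues)
        native_set = native_set[keep]
        if len(native_set) == 0:
            raise ValueError("no native contacts involve the requested residues")
    return float(_ensemble_counts(frames, native_set, definition.cutoff).mean())


def phi(mean_TS_mut: float, mean_TS_wt: float, mean_F_mut: float,
        mean_F_wt: float, eps: float = 0.5, mutant_id: str = "",
        n_frames: dict | None = None) -> PhiResult:
    """Exact contact-ratio phi; |denominator| < eps marks it undefined."""
    num = mean_TS_mut - mean_TS_wt
    den = mean_F_mut - mean_F_wt
    undefined = abs(den) < eps
    value = np.nan if undefined else num / den
    out_of_range = (not undefined) and not (0.0 <= value <= 1.0)
    return PhiResult(mutant_id, mean_TS_mut, mean_TS_wt, mean_F_mut, mean_F_wt,
                     num, den, float(value), undefined, out_of_range,
                     n_frames or {})


def phi_batch(wt_ensembles: dict, mutant_ensembles: dict,
              native_set: np.ndarray,
              definition: ContactDefinition = ContactDefinition(),
              eps: float = 0.5, mutant_sites: dict | None = None,
              mutant_native_sets: dict | None = None) -> list[PhiResult]:
    """phi for every mutant against shared wild-type TS and F ensembles.

    ``wt_ensembles`` is ``{"TS": frames, "F": frames}``;
    ``mutant_ensembles`` maps mutant_id to the same structure. Results are
    ordered by mutant_id; a failure in one mutant is isolated (recorded as
    an undefined result) and does not stop the batch.

    ``mutant_sites`` (optional, {mutant_id: residue index or list})
    switches that mutant's count to the residue-local contact variant;
    ``mutant_native_sets`` (optional, {mutant_id: (P, 2) pairs}) evaluates
    the mutant's ensembles against a per-mutant native set instead of the
    shared wild-type set.
    """
    native_set = np.asarray(native_set, dtype=int)
    results = []
    for mid in sorted(mutant_ensembles):
        try:
            sites = (mutant_sites or {}).get(mid)
            mut_set = np.asarray((mutant_native_sets or {}).get(mid, native_set),
                                 dtype=int)
            ts_wt = ensemble_mean_contacts(wt_ensembles["TS"], native_set,
                                           definition, residues=sites)
            f_wt = ensemble_mean_contacts(wt_ensembles["F"], native_set,
                                          definition, residues=sites)
            ens = mutant_ensembles[mid]
            ts_mut = ensemble_mean_contacts(ens["TS"], mut_set, definition,
                                            residues=sites)
            f_mut = ensemble_mean_contacts(ens["F"], mut_set, definition,
                                           residues=sites)
            n = {"TS_mut": len(ens["TS"]), "F_mut": len(ens["F"]),
                 "TS_wt": len(wt_ensembles["TS"]), "F_wt": len(wt_ensembles["F"])}
            results.append(phi(ts_mut, ts_wt, f_mut, f_wt, eps=eps,
                               mutant_id=str(mid), n_frames=n))
        except Exception as err:  # isolate per-mutant failures
            results.append(PhiResult(str(mid), np.nan, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, np.nan, True, False,
                                     {"error": str(err)}))
    return results


def phi_table(results: list[PhiResult]) -> pd.DataFrame:
    """Summary table (one row per mutant) for reporting / CSV export."""
    rows = []
    for r in results:
        rows.append({
            "mutant_id": r.mutant_id,
            "mean_TS_mut": r.mean_TS_mut, "mean_TS_wt": r.mean_TS_wt,
            "mean_F_mut": r.mean_F_mut, "mean_F_wt": r.mean_F_wt,
            "numerator": r.numerator, "denominator": r.denominator,
            "phi": r.phi, "undefined": r.undefined,
            "out_of_range": r.out_of_range,
        })
    return pd.DataFrame(rows)
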
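"""Benchmarking: match predictions to ground truth, recall/precision grids.

A predicted recombination event is *correct* when its destination branch
carries a non-nullified true event whose locus range intersects the
prediction's (overlap counting, not bijective matching: one truth event
may validate several predictions and vice versa).  Recall is the
fraction of non-nullified true events hit by at least one prediction;
precision is the fraction of predictions hitting at least one true
event.  Out-group predictions are excluded — the simulator's donors are
always in the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import EventCall, Weights
from .model import HreModel, HreResults
from .simulate import SimConfig, SimResult, TrueEvent, simulate
from .tree import PhyloTree, homoplastic_loci


def predicted_intervals(results: HreResults) -> list[tuple[int, frozenset[int]]]:
    """In-tree recombination predictions as (destination node, locus set)."""
    out = []
    for ev in results.hre_calls():
        snps = results.blocks.blocks[ev.block_id].snps
        loci = frozenset(snps[j].locus for j in range(ev.j_start, ev.j_end + 1))
        out.append((ev.dest_node, loci))
    return out


def match_predictions(
    predicted: Sequence[tuple[int, frozenset[int]]],
    truth: Sequence[TrueEvent],
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap matching on (same destination branch, intersecting loci).

    Returns boolean masks: per-prediction "hits some truth" and
    per-truth "hit by some prediction".  Nullified truth events must be
    discarded by the caller beforehand.
    """
    pred_ok = np.zeros(len(predicted), dtype=bool)
    truth_ok = np.zeros(len(truth), dtype=bool)
    for pi, (dest, loci) in enumerate(predicted):
        for ti, ev in enumerate(truth):
            if ev.branch != dest:
                continue
            if any(ev.locus_start <= l <= ev.locus_end for l in loci):
                pred_ok[pi] = True
                truth_ok[ti] = True
    return pred_ok, truth_ok


def recall_precision(
    n_correct_truth: int, n_truth: int, n_correct_pred: int, n_pred: int
) -> tuple[float, float]:
    """Recall and precision with the 0/0 := 1 convention for empty sets."""
    recall = n_correct_truth / n_truth if n_truth else 1.0
    precision = n_correct_pred / n_pred if n_pred else 1.0
    return recall, precision


def count_homoplastic(tree: PhyloTree, leaf_matrix: np.ndarray) -> int:
    """Loci whose allele pattern conflicts with vertical inheritance
    (minimum changes exceed #observed alleles - 1)."""
    return int(homoplastic_loci(tree, np.asarray(leaf_matrix)).sum())


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    config: SimConfig
    reps: int
    recall: float                  # pooled over replicates
    precision: float
    recall_mean: float             # mean of per-replicate rates
    precision_mean: float
    n_truth: int
    n_pred: int
    n_correct_truth: int
    n_correct_pred: int
    per_rep: Optional[pd.DataFrame] = None

    @property
    def recall_undeduplicated(self) -> float:
        """Alternative recall convention: count every correct *prediction*
        against the truth total, without deduplicating predictions that hit
        the same true event."""
        return self.n_correct_pred / self.n_truth if self.n_truth else 1.0


def detect(sim: SimResult, weights: Optional[Weights] = None,
           outgroup: bool = True) -> HreResults:
    """Run the full detection pipeline on a simulation's observed output."""
    model = HreModel(sim.to_snp_data(), sim.tree, weights=weights, outgroup=outgroup)
    return model.fit()


def run_experiment(
    config: SimConfig,
    reps: int,
    seed: int,
    weights: Optional[Weights] = None,
    outgroup: bool = True,
    keep_per_rep: bool = False,
) -> ExperimentResult:
    """Simulate -> detect -> match, ``reps`` times, pooling the counts."""
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    tot_truth = tot_pred = tot_ct = tot_cp = 0
    rows = []
    recalls, precisions = [], []
    for r in range(reps):
        rng = np.random.default_rng(child_seeds[r])
        sim = simulate(config, rng)
        results = detect(sim, weights=weights, outgroup=outgroup)
        truth = sim.true_hres()
        preds = predicted_intervals(results)
        pred_ok, truth_ok = match_predictions(preds, truth)
        ct, cp = int(truth_ok.sum()), int(pred_ok.sum())
        tot_truth += len(truth)
        tot_pred += len(preds)
        tot_ct += ct
        tot_cp += cp
        rec, prec = recall_precision(ct, len(truth), cp, len(preds))
        recalls.append(rec)
        precisions.append(prec)
        if keep_per_rep:
            rows.append(
                {"rep": r, "n_truth": len(truth), "n_pred": len(preds),
                 "n_correct_truth": ct, "n_correct_pred": cp,
                 "recall": rec, "precision": prec}
            )
    recall, precision = recall_precision(tot_ct, tot_truth, tot_cp, tot_pred)
    return ExperimentResult(
        config=config, reps=reps, recall=recall, precision=precision,
        recall_mean=float(np.mean(recalls)), precision_mean=float(np.mean(precisions)),
        n_truth=tot_truth, n_pred=tot_pred,
        n_correct_truth=tot_ct, n_correct_pred=tot_cp,
        per_rep=pd.DataFrame(rows) if keep_per_rep else None,
    )


def run_grid(
    base: SimConfig,
    param: str,
    values: Sequence,
    reps: int,
    seed: int,
    weights: Optional[Weights] = None,
    outgroup: bool = True,
) -> pd.DataFrame:
    """Vary one simulator parameter, keeping the others at the baseline."""
    rows = []
    for i, value in enumerate(values):
        config = replace(base, **{param: value})
        res = run_experiment(
            config, reps, seed + i, weights=weights, outgroup=outgroup
        )
        rows.append(
            {
                "param": param, "value": value, "reps": reps,
                "recall": res.recall, "precision": res.precision,
                "recall_mean": res.recall_mean,
                "precision_mean": res.precision_mean,
                "n_truth": res.n_truth, "n_pred": res.n_pred,
            }
        )
    return pd.DataFrame(rows)
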
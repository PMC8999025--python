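"""Paired pre/post connectivity analysis as a Model / Results pair.

``PairedConnectivityModel`` holds one shift group's paired oxy-Hb recordings
(or precomputed connectivity matrices); ``fit()`` runs the full analysis —
per-subject Pearson connectivity, the group mean-COR comparison, edge-wise
paired t-tests with BH-FDR, the density-threshold sweep with nodal metrics,
and small-world analysis against degree-preserving random nulls — and
returns a ``PairedConnectivityResults`` carrying estimates, test statistics
and a ``summary()`` table.

Example
-------
>>> from nirsconn import synthetic, model
>>> truth_pre = synthetic.make_block_correlation(0.8, 0.3)
>>> truth_post = synthetic.make_block_correlation(0.6, 0.3)
>>> cohort = synthetic.generate_paired_cohort(17, truth_pre, truth_post, seed=7)
>>> res = model.PairedConnectivityModel.from_cohort(cohort).fit(seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import edge_stats as es
from . import graph_metrics as gm
from .errors import InvalidInputError
from .montage import Montage, load_default_montage
from .preprocess import HbTimeSeries, bandpass
from .synthetic import SyntheticCohort


class PairedConnectivityModel:
    """Paired-design resting-state connectivity analysis for one group.

    Parameters
    ----------
    pre, post : lists of HbTimeSeries, paired by position.
    montage : channel geometry/ROI metadata; default prefrontal 22-channel.
    group_label : free-text group tag carried into results tables.
    apply_bandpass : filter each series to the hemodynamic band before
        correlating (set False if the input is already preprocessed).
    """

    def __init__(self, pre: list[HbTimeSeries], post: list[HbTimeSeries],
                 montage: Montage | None = None, group_label: str = "",
                 apply_bandpass: bool = False):
        if len(pre) != len(post):
            raise InvalidInputError("paired design: pre and post subject counts differ")
        if len(pre) < 2:
            raise InvalidInputError("need at least 2 subjects")
        fs = {round(h.fs_hz, 9) for h in (*pre, *post)}
        if len(fs) != 1:
            raise InvalidInputError("all recordings must share the sampling rate")
        self.pre = pre
        self.post = post
        self.montage = montage if montage is not None else load_default_montage()
        self.group_label = group_label
        self.apply_bandpass = apply_bandpass

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, montage: Montage | None = None,
                    apply_bandpass: bool = True) -> "PairedConnectivityModel":
        return cls(cohort.pre, cohort.post, montage=montage,
                   group_label=cohort.group_label, apply_bandpass=apply_bandpass)

    @property
    def n_subjects(self) -> int:
        return len(self.pre)

    def _cor(self, hb: HbTimeSeries) -> conn.ConnectivityMatrix:
        if self.apply_bandpass:
            hb = HbTimeSeries(bandpass(hb.values, hb.fs_hz), fs_hz=hb.fs_hz,
                              chromophore=hb.chromophore, subject_id=hb.subject_id,
                              session=hb.session)
        mat = conn.cor_matrix(hb)
        mat.group_label = self.group_label
        return mat

    def fit(self, r_threshold: float = 0.7, fdr_q: float = 0.05,
            thresholds=gm.DEFAULT_THRESHOLDS, n_null: int = 100,
            smallworld_T: float = 0.3, seed: int = 0,
            compute_graph: bool = True) -> "PairedConnectivityResults":
        """Run the full paired analysis.

        smallworld_T : density threshold at which the group-level small-world
            coefficients are computed (one point of the sweep).
        n_null : matched degree-preserving random networks per small-world
            evaluation.
        """
        cor_pre = [self._cor(h) for h in self.pre]
        cor_post = [self._cor(h) for h in self.post]
        mean_pre = conn.group_mean_cor(cor_pre, group_label=self.group_label, session="pre")
        mean_post = conn.group_mean_cor(cor_post, group_label=self.group_label, session="post")

        mc_pre = np.array([conn.mean_cor_scalar(m) for m in cor_pre])
        mc_post = np.array([conn.mean_cor_scalar(m) for m in cor_post])
        mc_t, mc_p = es.paired_t(mc_pre, mc_post)

        samples = es.PairedEdgeSamples.from_matrices(cor_pre, cor_post,
                                                     group_label=self.group_label)
        edge_result = es.edgewise_paired_test(samples, q=fdr_q)

        net_pre = conn.binarize(mean_pre, r_threshold)
        net_post = conn.binarize(mean_post, r_threshold)

        profiles_pre = profiles_post = None
        nodal_bc = nodal_eloc = None
        sw_pre = sw_post = None
        if compute_graph:
            profiles_pre = [gm.metric_sweep(m, thresholds) for m in cor_pre]
            profiles_post = [gm.metric_sweep(m, thresholds) for m in cor_post]
            nodal_bc = gm.nodal_group_comparison(profiles_pre, profiles_post, "nodal_bc")
            nodal_eloc = gm.nodal_group_comparison(profiles_pre, profiles_post, "nodal_eloc")
            rng = np.random.default_rng(seed)
            sw_pre = gm.small_worldness(gm.density_threshold(mean_pre, smallworld_T),
                                        n_null=n_null, seed=int(rng.integers(2**31 - 1)))
            sw_post = gm.small_worldness(gm.density_threshold(mean_post, smallworld_T),
                                         n_null=n_null, seed=int(rng.integers(2**31 - 1)))

        return PairedConnectivityResults(
            model=self, cor_pre=cor_pre, cor_post=cor_post,
            group_mean_pre=mean_pre, group_mean_post=mean_post,
            mean_cor_pre=mc_pre, mean_cor_post=mc_post,
            mean_cor_t=mc_t, mean_cor_p=mc_p,
            edge_result=edge_result,
            network_pre=net_pre, network_post=net_post,
            profiles_pre=profiles_pre, profiles_post=profiles_post,
            nodal_bc=nodal_bc, nodal_eloc=nodal_eloc,
            smallworld_pre=sw_pre, smallworld_post=sw_post,
            r_threshold=r_threshold, fdr_q=fdr_q,
            thresholds=np.asarray(thresholds, dtype=float),
            smallworld_T=smallworld_T, n_null=n_null, seed=seed,
        )


@dataclass
class PairedConnectivityResults:
    """Estimates and test statistics from PairedConnectivityModel.fit()."""

    model: PairedConnectivityModel
    cor_pre: list
    cor_post: list
    group_mean_pre: conn.ConnectivityMatrix
    group_mean_post: conn.ConnectivityMatrix
    mean_cor_pre: np.ndarray
    mean_cor_post: np.ndarray
    mean_cor_t: float
    mean_cor_p: float
    edge_result: es.EdgeTestResult
    network_pre: conn.BinaryNetwork
    network_post: conn.BinaryNetwork
    profiles_pre: list | None
    profiles_post: list | None
    nodal_bc: pd.DataFrame | None
    nodal_eloc: pd.DataFrame | None
    smallworld_pre: gm.SmallWorldResult | None
    smallworld_post: gm.SmallWorldResult | None
    r_threshold: float
    fdr_q: float
    thresholds: np.ndarray
    smallworld_T: float
    n_null: int
    seed: int

    @property
    def n_significant_edges(self) -> int:
        return int(self.edge_result.q_significant.sum())

    def edge_frame(self) -> pd.DataFrame:
        return self.edge_result.to_frame()

    def summary(self) -> str:
        g = self.model.group_label or "group"
        lines = [
            "Paired resting-state connectivity analysis",
            "=" * 46,
            f"group: {g}    subjects: {self.model.n_subjects} (paired pre/post)",
            "",
            f"mean COR pre : {self.mean_cor_pre.mean():.4f}",
            f"mean COR post: {self.mean_cor_post.mean():.4f}",
            f"paired t = {self.mean_cor_t:.3f}, p = {self.mean_cor_p:.4g}",
            "",
            f"edge-wise paired t-tests: {self.n_significant_edges} of "
            f"{self.edge_result.p.size} edges significant at BH-FDR q < {self.fdr_q}",
            f"binary network (r > {self.r_threshold}): "
            f"{self.network_pre.n_edges} edges pre, {self.network_post.n_edges} post",
        ]
        if self.smallworld_pre is not None:
            sp, ss = self.smallworld_pre, self.smallworld_post
            lines += [
                "",
                f"small-world at density T = {self.smallworld_T} "
                f"({self.n_null} degree-preserving nulls):",
                f"  pre : gamma = {sp.gamma:.3f}, lambda = {sp.lambda_:.3f}, sigma = {sp.sigma:.3f}",
                f"  post: gamma = {ss.gamma:.3f}, lambda = {ss.lambda_:.3f}, sigma = {ss.sigma:.3f}",
            ]
        if self.nodal_bc is not None:
            sig_bc = self.nodal_bc.loc[self.nodal_bc.significant, "channel"].tolist()
            sig_el = self.nodal_eloc.loc[self.nodal_eloc.significant, "channel"].tolist()
            lines += [
                "",
                f"nodal betweenness, p < 0.05 (uncorrected): {', '.join(sig_bc) or 'none'}",
                f"nodal local efficiency, p < 0.05 (uncorrected): {', '.join(sig_el) or 'none'}",
            ]
        return "\n".join(lines)

    def plot_group_matrices(self, path=None):
        """Heat-maps of the pre/post group-mean connectivity (needs matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, mat, title in zip(axes, (self.group_mean_pre, self.group_mean_post),
                                  ("pre", "post")):
            im = ax.imshow(mat.values, vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_title(f"{self.model.group_label} {title}")
        fig.colorbar(im, ax=axes.tolist(), shrink=0.8, label="COR")
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig
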
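"""Figures: polar plot of relative intrinsic activity across receptors."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["polar_rai_plot"]


def polar_rai_plot(rai_by_ligand: dict, outfile=None, log_scale: bool = True):
    """Polar plot of RA_i ratios normalised per ligand.

    ``rai_by_ligand`` maps ligand name -> {construct: RA_i}.  For each ligand
    the RA_i values are divided by the RA_i at the construct with the lowest
    activity, so every trace has minimum 1 and the radius shows fold
    preference between receptors.
    """
    constructs = sorted({c for d in rai_by_ligand.values() for c in d})
    theta = np.linspace(0.0, 2.0 * np.pi, len(constructs), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for ligand, d in rai_by_ligand.items():
        vals = np.array([d[c] for c in constructs], dtype=float)
        positive = vals[vals > 0]
        if positive.size == 0:
            continue
        ratios = np.where(vals > 0, vals / positive.min(), np.nan)
        r = np.log10(ratios) if log_scale else ratios
        ax.plot(np.append(theta, theta[0]), np.append(r, r[0]), marker="o",
                label=ligand)
    ax.set_xticks(theta)
    ax.set_xticklabels(constructs)
    ax.set_title("relative intrinsic activity "
                 + ("(log10 fold over lowest)" if log_scale else
                    "(fold over lowest)"))
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    if outfile is not None:
        fig.savefig(outfile, bbox_inches="tight")
        plt.close(fig)
    return fig
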
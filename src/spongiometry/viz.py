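"""Optional plotting helpers (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

from .morphometry import AverageProfile, LineProfileSet, MorphometryResult


def plot_profile(
    profile: AverageProfile,
    result: MorphometryResult | None = None,
    profile_set: LineProfileSet | None = None,
    path: str | Path | None = None,
):
    """Average profile with landmark annotations; individual lines in grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if profile_set is not None:
        ax.plot(profile_set.depths, profile_set.profiles.T, color="0.85", lw=0.5, zorder=1)
    ax.plot(profile.depths, profile.values, color="C0", lw=2, zorder=2, label="average")
    if result is not None:
        ax.plot(result.ps_depth, result.ps_value, "v", color="C2", label="primary spongiosa")
        ax.plot(result.ss_depth, result.ss_value, "^", color="C1", label="secondary spongiosa")
    ax.set_xlabel("depth from growth-plate boundary (mm)")
    ax.set_ylabel("relaxation time (ms)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
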
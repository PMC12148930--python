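"""Combination-index analysis of dual splicing-factor perturbation.

Simulates replicate PSI for control / MBNL-depleted / SRRM-depleted / double
depletion with planted synergy (1.25x the Bliss expectation), antagonism and
independence, then classifies each event by CI = (EA + EB - EA*EB) / EAB.
"""

from pathlib import Path

from misplice.dose import effects_from_psi_table, synergy_frame, synergy_summary
from misplice.simulate import simulate_dual_perturbation

RES = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = RES / "synergy"
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_dual_perturbation(
        60, noise_sd=0.01, n_reps=4, seed=1, synergy_factor=1.25
    )
    table.to_csv(out / "perturbation_psi.tsv", sep="\t", index=False)
    res = synergy_frame(synergy_summary(effects_from_psi_table(table, mode="concordant")))
    res = res.merge(truth[["event_id", "class"]], on="event_id").rename(
        columns={"class": "true_class"}
    )
    res.to_csv(out / "synergy_calls.tsv", sep="\t", index=False)

    for cls in ("independent", "synergistic", "antagonistic"):
        sub = res[res["true_class"] == cls]
        correct = (sub["classification"] == cls).mean()
        print(
            f"{cls:>12}: n = {len(sub):2d}, mean CI = {sub['ci_mean'].mean():.3f} "
            f"(sd {sub['ci_sd'].mean():.3f}), correctly classified {correct * 100:.0f}%"
        )


if __name__ == "__main__":
    main()
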
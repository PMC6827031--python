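#!/usr/bin/env python
"""Rank variables by jackknife gain and recover the true driver.

Two analyses on synthetic studies whose generating truth is known
(distance to road dominant, soil type secondary):

1. one full jackknife (with-only / without / all gains) plus permutation
   contributions and the correlation-screened variable selection on the
   seed-1 study;
2. the recovery experiment: with-only rankings across 20 independently
   generated studies, reporting how often the true driver ranks first.
"""

import argparse
from pathlib import Path

from pikasdm import evaluation as ev
from pikasdm import experiments as ex
from pikasdm import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results/importance"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = sd.generate_study(seed=args.seed)
    pres = study.presences.features_presence
    bg = study.presences.features_background
    kinds = study.stack.kinds()
    jk = ev.jackknife(pres, bg, kinds, settings=ex.EXPERIMENT_SETTINGS)
    model, _ = ev._fit_gain(pres, bg, kinds, study.stack.names,
                            ex.EXPERIMENT_SETTINGS)
    contrib = ev.contribution(model, pres, bg, seed=args.seed)
    table = jk.gains.set_index("variable")
    table["contribution_pct"] = contrib
    table.to_csv(args.out / "jackknife.csv")
    retained = ev.select_variables(pres, bg, kinds, jk,
                                   settings=ex.EXPERIMENT_SETTINGS, seed=args.seed)

    print(f"seed-{args.seed} study; all-variables gain "
          f"{jk.gain_all_variables:.4f}")
    print(table.sort_values("gain_with_only", ascending=False)
          .round(4).to_string())
    print(f"retained after |r|>0.75 screening and <0.5% contribution cut: "
          f"{retained}")

    recovery = ex.jackknife_recovery(seeds=range(args.seed, args.seed + args.n_seeds))
    recovery.table.to_csv(args.out / "recovery.csv", index=False)
    print(f"\nrecovery across {args.n_seeds} studies: "
          f"'{recovery.true_variable}' ranks first by with-only gain in "
          f"{100 * recovery.top_rate:.0f}% of seeds")


if __name__ == "__main__":
    main()
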
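#!/usr/bin/env python
"""Fit the prognostic scores on the training cohort.

Normalizes the 142 features with training-cohort Z-scores, then fits:
the feature score (LASSO-Cox with cross-validated penalty), the
architecture score (ridge-Cox over the eight archetype indicators), the
clinical score (unpenalized Cox over the clinical covariates), and the
Cox-weighted combinations (feature+architecture and the full model).

Reads results/cohort.csv; writes model JSONs under results/models/ and
results/scored_cohort.csv with one score column per model.
"""

import argparse
import warnings
from pathlib import Path

from fiberscore import (
    apply_normalizer,
    combine_scores,
    fit_cli_cox,
    fit_lasso_cox,
    fit_normalizer,
    read_cohort,
    write_score_model,
)
from fiberscore.registry import TCMF_COLUMNS, feature_name
from fiberscore.scoring import fit_tacs_score

warnings.filterwarnings("ignore")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--folds", type=int, default=5)
    parser.add_argument("--lambda-rule", choices=("min", "1se"), default="min")
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    model_dir = args.out_dir / "models"
    model_dir.mkdir(parents=True, exist_ok=True)

    table = read_cohort(args.cohort)
    norm = fit_normalizer(table)
    normalized = apply_normalizer(norm, table)
    train = normalized.subset("training")
    t, e = train.outcomes()
    kept = [c for c in TCMF_COLUMNS if c in normalized.df.columns]

    tcmf = fit_lasso_cox(train.df[kept], t, e, cv_folds=args.folds,
                         lambda_rule=args.lambda_rule, seed=args.seed,
                         normalization=norm)
    print(f"feature score: {len(tcmf.feature_names)} of {len(kept)} features "
          f"selected at lambda={tcmf.metadata['lambda']:.4g}")
    for name, coef in zip(tcmf.feature_names, tcmf.coefficients):
        print(f"  {feature_name(name):42s} {coef:+.4f}")

    tacs = fit_tacs_score(train.df, t, e, cv_folds=args.folds, seed=args.seed)
    print(f"architecture score: ridge penalty {tacs.metadata['penalty']:.4g}, "
          f"coefficients {[round(c, 3) for c in tacs.coefficients]}")

    cli = fit_cli_cox(train.df, t, e)
    print(f"clinical score: {len(cli.feature_names)} contrasts")

    scored = normalized.df.copy()
    scored["tcmf_score"] = tcmf.score(normalized.df)
    scored["tacs_score"] = tacs.score(normalized.df)
    scored["cli_score"] = cli.score(normalized.df)

    train_scored = scored[scored["cohort"] == "training"]
    tt, te = train_scored["dfs_months"].to_numpy(), train_scored["event"].to_numpy()
    duo = combine_scores(train_scored, ("tcmf_score", "tacs_score"), tt, te)
    full = combine_scores(train_scored, ("cli_score", "tcmf_score", "tacs_score"), tt, te)
    scored["tcmf_tacs_score"] = duo.score(scored)
    scored["full_score"] = full.score(scored)
    print(f"combination weights (feature+architecture): "
          f"{dict(zip(duo.feature_names, duo.coefficients.round(3)))}")
    print(f"combination weights (full): "
          f"{dict(zip(full.feature_names, full.coefficients.round(3)))}")

    for name, model in (("tcmf", tcmf), ("tacs", tacs), ("cli", cli),
                        ("tcmf_tacs", duo), ("full", full)):
        write_score_model(model, model_dir / f"{name}.json")
    scored.to_csv(args.out_dir / "scored_cohort.csv", index=False)
    print(f"wrote {model_dir}/*.json and {args.out_dir / 'scored_cohort.csv'}")


if __name__ == "__main__":
    main()
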
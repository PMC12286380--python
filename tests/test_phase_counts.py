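import math
import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from callseq.events_io import Phase, SessionRecord
from callseq.phase_counts import (
    CountModelFit,
    PhaseCountRow,
    _design,
    _laplace_loglik,
    count_calls_by_phase,
    counts_to_frame,
    fit_count_model,
    select_model_aic,
)
from conftest import make_event


def synthetic_rows(seed, phase_effect=0.0, subject_sd=0.3, trial_sd=0.2,
                   n_subjects=6, n_trials=10, base=30.0):
    rng = np.random.default_rng(seed)
    su = {f"B{i}": rng.normal(0, subject_sd) for i in range(n_subjects)}
    tu = {f"T{j}": rng.normal(0, trial_sd) for j in range(n_trials)}
    rows = []
    for s in su:
        for t in tu:
            for phase, eff in [
                (Phase.PRE, 0.0),
                (Phase.F2F, phase_effect),
                (Phase.POST, 0.0),
            ]:
                lam = math.exp(math.log(base) + eff + su[s] + tu[t])
                rows.append(PhaseCountRow(s, t, phase, int(rng.poisson(lam))))
    return rows


class TestCountCallsByPhase:
    def test_counts_per_phase_and_facing_excluded(self):
        events = (
            [make_event(i * 1.0, "A", phase=Phase.PRE) for i in range(3)]
            + [make_event(i * 1.0, "A", phase=Phase.F2F) for i in range(5)]
            + [make_event(i * 1.0 + 0.5, "B", phase=Phase.F2F) for i in range(4)]
            + [make_event(i * 1.0, "A", phase=Phase.POST) for i in range(2)]
        )
        rec = SessionRecord(session_id="S1", pair=("A", "B"), events=events)
        rows = {r.phase: r.n_calls for r in count_calls_by_phase([rec])}
        assert rows == {Phase.PRE: 3, Phase.F2F: 5, Phase.POST: 2}

    def test_silent_session_yields_zero_rows(self):
        rec = SessionRecord(session_id="S1", pair=("A", "B"), events=[])
        rows = count_calls_by_phase([rec])
        assert [r.n_calls for r in rows] == [0, 0, 0]

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            PhaseCountRow("A", "T1", Phase.PRE, -1)


class TestFitCountModel:
    def test_aic_identity(self):
        fit = fit_count_model(synthetic_rows(0), include_phase=True)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_parameters, abs=1e-6)

    def test_requires_multiple_subjects_and_trials(self):
        rows = [
            PhaseCountRow("A", "T1", Phase.PRE, 3),
            PhaseCountRow("A", "T1", Phase.F2F, 5),
        ]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_count_model(rows)

    def test_constant_counts_collapse_to_log_count_intercept(self):
        rows = [
            PhaseCountRow(s, t, p, 7)
            for s in ("A", "B", "C")
            for t in ("T1", "T2", "T3")
            for p in Phase
        ]
        fit = fit_count_model(rows, include_phase=False)
        assert fit.singular  # no between-subject/trial variance to absorb
        assert fit.fixed_effects["(Intercept)"] == pytest.approx(math.log(7), abs=1e-2)

    def test_zero_variance_limit_matches_plain_poisson_glm(self):
        """Collapsing the random effects recovers an ordinary Poisson regression."""
        import statsmodels.api as sm

        rows = synthetic_rows(1, phase_effect=0.3, subject_sd=0.0, trial_sd=0.0,
                              n_subjects=3, n_trials=4)
        X, Z, y, names, n_subj, n_trial = _design(rows, include_phase=True)
        ll, beta, _ = _laplace_loglik(
            np.array([-12.0, -12.0]), X, Z, y, n_subj, n_trial
        )
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert ll == pytest.approx(glm.llf, abs=0.5)
        assert np.allclose(beta, glm.params, atol=5e-3)

    def test_matches_lme4_glmer_laplace(self, tmp_path):
        """Independent cross-check of the Laplace marginal likelihood."""
        rows = synthetic_rows(42, phase_effect=math.log(1.5))
        frame = counts_to_frame(rows)
        csv = tmp_path / "counts.csv"
        frame.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            d$phase <- relevel(factor(d$phase, levels=c('PRE','F2F','POST')), ref='PRE')
            m <- glmer(n_calls ~ phase + (1|subject_id) + (1|trial_id),
                       data=d, family=poisson)
            cat(as.numeric(logLik(m)), fixef(m)['phaseF2F'], sep='\\n')
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_loglik, r_coef = map(float, out.stdout.strip().split("\n"))
        fit = fit_count_model(rows, include_phase=True)
        assert fit.loglik == pytest.approx(r_loglik, abs=0.05)
        assert fit.fixed_effects["phase[F2F]"] == pytest.approx(r_coef, abs=1e-3)

    def test_recovers_phase_effect(self):
        coefs = [
            fit_count_model(
                synthetic_rows(seed, phase_effect=math.log(1.5)), include_phase=True
            ).fixed_effects["phase[F2F]"]
            for seed in range(3)
        ]
        assert np.median(np.abs(np.array(coefs) - math.log(1.5))) < 0.15

    def test_monotone_response_to_scaled_f2f_counts(self):
        rows = synthetic_rows(3, phase_effect=0.0)
        scaled = [
            PhaseCountRow(
                r.subject_id,
                r.trial_id,
                r.phase,
                r.n_calls * 2 if r.phase is Phase.F2F else r.n_calls,
            )
            for r in rows
        ]
        coef = fit_count_model(rows).fixed_effects["phase[F2F]"]
        coef_scaled = fit_count_model(scaled).fixed_effects["phase[F2F]"]
        assert coef_scaled > coef


class TestSelectModelAic:
    @staticmethod
    def dummy_fit(aic, include_phase, k=5, fingerprint=("x",)):
        return CountModelFit(
            fixed_effects={},
            random_intercept_variances={},
            loglik=-(aic - 2 * k) / 2,
            n_parameters=k,
            singular=False,
            converged=True,
            include_phase=include_phase,
            data_fingerprint=fingerprint,
        )

    def test_published_aic_pair_delta(self):
        phase = self.dummy_fit(4221.3, True)
        null = self.dummy_fit(4486.9, False)
        best, table = select_model_aic([phase, null])
        assert best is phase
        assert table.loc[table["model"] == "null", "delta_aic"].item() == pytest.approx(
            265.6, abs=1e-9
        )

    def test_single_fit_has_zero_delta(self):
        fit = self.dummy_fit(100.0, True)
        best, table = select_model_aic([fit])
        assert best is fit and table["delta_aic"].tolist() == [0.0]

    def test_exact_tie_goes_to_first_and_is_recorded(self):
        a, b = self.dummy_fit(100.0, True), self.dummy_fit(100.0, False)
        best, table = select_model_aic([a, b])
        assert best is a
        assert table["tied"].tolist() == [False, True]

    def test_differing_data_refused(self):
        a = self.dummy_fit(100.0, True, fingerprint=("x",))
        b = self.dummy_fit(90.0, False, fingerprint=("y",))
        with pytest.raises(ValueError, match="differing data"):
            select_model_aic([a, b])
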
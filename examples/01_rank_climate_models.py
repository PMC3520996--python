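"""Rank candidate climate models against an observed SST baseline.

Builds the observed coarse-resolution winter climatology, simulates six
candidate models with increasing error, scores each with the four
validation statistics (bias, pattern correlation, RMSE, centred RMSE),
ranks them, and screens a deliberately poor model with the
leave-one-out outlier analysis.
"""

from abaclim import (RasterGrid, generate_gcm_anomalies,
                     generate_gcm_historical, outlier_analysis, rank_models,
                     skill_stats, study_domain)
from abaclim.synthetic import SyntheticTruth, baseline_surface, coarse_geometry_for

truth = SyntheticTruth()
fine_geom, _ = study_domain()
coarse_geom = coarse_geometry_for(fine_geom)
observed = RasterGrid(values=baseline_surface(coarse_geom, "august", truth),
                      geometry=coarse_geom, variable="sst_august")

historical = generate_gcm_historical(observed, n_models=6, seed=1)
tables = {name: skill_stats(field, observed)
          for name, field in historical.items()}
ranking = rank_models(tables)
print("skill ranking (rank 1 = best per statistic, smaller cumulative "
      "rank = better overall):")
print(ranking.round(3).to_string())

anomalies, planted = generate_gcm_anomalies(
    n_models=6, decades=[2050, 2100], scenario="WRE750", truth=truth,
    outlier_bias=3.0, seed=2)
outliers = outlier_analysis(anomalies)
print("\noutlier screen (score = mean departure from the other models, "
      "°C; the planted outlier was", planted + "):")
print(outliers.round(3).to_string())
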
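# Normative maximal oxygen uptake (VO2max, ml·kg^-1·min^-1) by gender, decadal age
# bracket and cardiorespiratory fitness category.
# PROVENANCE: these are representative values following the standard fitness-
# classification convention of exercise-physiology normative tables (graded-exercise-test
# population norms). They are EXTERNAL REFERENCE DATA shipped for convenience, not model
# output; any measured or assumed VO2max supplied via `vo2max_override` takes precedence.
# Brackets are clamped at the extremes (ages below 10-19 use 10-19; above 70-79 use 70-79).
gender,age_lo,age_hi,category,vo2max_ml_kg_min
male,10,19,poor,35.0
male,10,19,fair,39.9
male,10,19,good,44.2
male,10,19,excellent,51.0
male,10,19,superior,56.0
male,20,29,poor,33.0
male,20,29,fair,36.5
male,20,29,good,42.5
male,20,29,excellent,46.5
male,20,29,superior,52.5
male,30,39,poor,31.5
male,30,39,fair,35.5
male,30,39,good,41.0
male,30,39,excellent,45.0
male,30,39,superior,49.5
male,40,49,poor,30.2
male,40,49,fair,33.6
male,40,49,good,38.9
male,40,49,excellent,43.8
male,40,49,superior,48.0
male,50,59,poor,26.1
male,50,59,fair,31.0
male,50,59,good,35.8
male,50,59,excellent,41.0
male,50,59,superior,45.3
male,60,69,poor,20.5
male,60,69,fair,26.1
male,60,69,good,32.3
male,60,69,excellent,36.5
male,60,69,superior,44.2
male,70,79,poor,18.0
male,70,79,fair,23.1
male,70,79,good,28.0
male,70,79,excellent,32.0
male,70,79,superior,38.0
female,10,19,poor,25.0
female,10,19,fair,31.0
female,10,19,good,35.0
female,10,19,excellent,39.0
female,10,19,superior,42.0
female,20,29,poor,23.6
female,20,29,fair,29.0
female,20,29,good,33.0
female,20,29,excellent,37.0
female,20,29,superior,41.0
female,30,39,poor,22.8
female,30,39,fair,27.0
female,30,39,good,31.5
female,30,39,excellent,35.7
female,30,39,superior,40.0
female,40,49,poor,21.0
female,40,49,fair,24.5
female,40,49,good,29.0
female,40,49,excellent,32.9
female,40,49,superior,36.9
female,50,59,poor,20.2
female,50,59,fair,22.8
female,50,59,good,27.0
female,50,59,excellent,31.5
female,50,59,superior,35.7
female,60,69,poor,17.5
female,60,69,fair,20.2
female,60,69,good,24.5
female,60,69,excellent,28.0
female,60,69,superior,32.0
female,70,79,poor,16.0
female,70,79,fair,18.5
female,70,79,good,22.0
female,70,79,excellent,25.0
female,70,79,superior,29.0
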
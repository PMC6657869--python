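# Transcription of the published stage-2 model-selection tables (best
# models, delta AIC <= 2). table: effect_screened / effect_complete are the
# effect-size response (screened-trait and all-species trait groups);
# scale_screened / scale_complete are the scale-of-effect response.
# Transcribed values, not computed by this package.
table,model,k,aic,delta,w
effect_screened,Fledglings per clutch,3,362.15,0.00,0.30
effect_screened,Clutch size,3,362.53,0.38,0.25
effect_screened,Migratory status,3,363.03,0.88,0.19
effect_screened,Fledglings per clutch + migratory status,4,363.76,1.61,0.13
effect_screened,Fledglings per clutch + frugivory,4,363.82,1.67,0.13
effect_complete,Granivory,3,716.48,0.00,0.27
effect_complete,Cavity nesting + granivory,4,717.60,1.12,0.15
effect_complete,Clutch size + granivory,4,717.65,1.18,0.15
effect_complete,Granivory + migratory status,4,718.14,1.67,0.12
effect_complete,Migratory status,3,718.36,1.88,0.10
effect_complete,Frugivory + Granivory,4,718.36,1.89,0.10
effect_complete,Clutch size,3,718.39,1.91,0.10
scale_screened,Frugivory,3,168.33,0.00,0.13
scale_screened,Frugivory + granivory,4,168.82,0.49,0.10
scale_screened,Wingspan,3,168.91,0.58,0.10
scale_screened,Clutch size + frugivory,4,168.99,0.66,0.09
scale_screened,Granivory,3,169.23,0.90,0.08
scale_screened,Flock size + frugivory,4,169.41,1.08,0.07
scale_screened,Omnivory,3,169.41,1.08,0.07
scale_screened,Granivory + wingspan,4,169.48,1.15,0.07
scale_screened,Cavity nesting + frugivory,4,169.50,1.17,0.07
scale_screened,Cavity nesting,3,169.88,1.55,0.06
scale_screened,Frugivory + wingspan,4,170.17,1.84,0.05
scale_screened,Flock size + wingspan,4,170.28,1.95,0.05
scale_screened,Omnivory + wingspan,4,170.30,1.97,0.05
scale_complete,Frugivory + granivory,4,369.40,0.00,0.21
scale_complete,Granivory + omnivory,4,369.43,0.03,0.20
scale_complete,Granivory,3,369.48,0.08,0.20
scale_complete,Omnivory,3,370.04,0.64,0.15
scale_complete,Clutch size + frugivory + granivory,5,371.17,1.77,0.09
scale_complete,Cavity nesting + granivory,4,371.27,1.87,0.08
scale_complete,Frugivory + granivory + omnivory,5,371.38,1.98,0.08
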
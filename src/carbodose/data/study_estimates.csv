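study_id,parameter,estimate,uncertainty_value,uncertainty_kind,n_subjects
ref1,CL,8.33,19.1,RSE_percent,
ref1,V1,16.3,17,RSE_percent,
ref1,K12,0.104,37.8,RSE_percent,
ref1,K21,0.171,49.2,RSE_percent,
ref2,CL,6.99,0.74,SE,
ref2,V1,14.4,0.99,SE,
ref2,V2,24.8,0.46,SE,
ref2,Q,1.22,2.7,SE,
ref3,CL,8.38,1.41,RSE_percent,
ref3,V1,15.4,1.79,RSE_percent,
ref3,K12,0.135,7.85,RSE_percent,
ref3,K21,0.215,5.91,RSE_percent,
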
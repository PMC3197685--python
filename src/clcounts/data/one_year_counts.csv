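patient_id,arm,timepoint_months,new_cl_count
no_therapy_001,no_therapy,12,0
no_therapy_002,no_therapy,12,0
no_therapy_003,no_therapy,12,0
no_therapy_004,no_therapy,12,0
no_therapy_005,no_therapy,12,0
no_therapy_006,no_therapy,12,0
no_therapy_007,no_therapy,12,0
no_therapy_008,no_therapy,12,0
no_therapy_009,no_therapy,12,0
no_therapy_010,no_therapy,12,0
no_therapy_011,no_therapy,12,0
no_therapy_012,no_therapy,12,0
no_therapy_013,no_therapy,12,0
no_therapy_014,no_therapy,12,0
no_therapy_015,no_therapy,12,1
no_therapy_016,no_therapy,12,1
no_therapy_017,no_therapy,12,1
no_therapy_018,no_therapy,12,1
no_therapy_019,no_therapy,12,1
no_therapy_020,no_therapy,12,1
no_therapy_021,no_therapy,12,1
no_therapy_022,no_therapy,12,2
no_therapy_023,no_therapy,12,2
no_therapy_024,no_therapy,12,2
no_therapy_025,no_therapy,12,2
no_therapy_026,no_therapy,12,2
no_therapy_027,no_therapy,12,2
no_therapy_028,no_therapy,12,2
no_therapy_029,no_therapy,12,2
no_therapy_030,no_therapy,12,2
no_therapy_031,no_therapy,12,2
no_therapy_032,no_therapy,12,2
no_therapy_033,no_therapy,12,2
no_therapy_034,no_therapy,12,2
no_therapy_035,no_therapy,12,2
no_therapy_036,no_therapy,12,2
no_therapy_037,no_therapy,12,2
no_therapy_038,no_therapy,12,2
no_therapy_039,no_therapy,12,2
no_therapy_040,no_therapy,12,2
no_therapy_041,no_therapy,12,2
no_therapy_042,no_therapy,12,2
no_therapy_043,no_therapy,12,3
no_therapy_044,no_therapy,12,3
no_therapy_045,no_therapy,12,3
no_therapy_046,no_therapy,12,3
no_therapy_047,no_therapy,12,3
no_therapy_048,no_therapy,12,3
no_therapy_049,no_therapy,12,3
no_therapy_050,no_therapy,12,4
no_therapy_051,no_therapy,12,4
sc_ifn_beta1a_001,sc_ifn_beta1a,12,0
sc_ifn_beta1a_002,sc_ifn_beta1a,12,0
sc_ifn_beta1a_003,sc_ifn_beta1a,12,0
sc_ifn_beta1a_004,sc_ifn_beta1a,12,0
sc_ifn_beta1a_005,sc_ifn_beta1a,12,0
sc_ifn_beta1a_006,sc_ifn_beta1a,12,0
sc_ifn_beta1a_007,sc_ifn_beta1a,12,0
sc_ifn_beta1a_008,sc_ifn_beta1a,12,0
sc_ifn_beta1a_009,sc_ifn_beta1a,12,0
sc_ifn_beta1a_010,sc_ifn_beta1a,12,0
sc_ifn_beta1a_011,sc_ifn_beta1a,12,0
sc_ifn_beta1a_012,sc_ifn_beta1a,12,0
sc_ifn_beta1a_013,sc_ifn_beta1a,12,0
sc_ifn_beta1a_014,sc_ifn_beta1a,12,0
sc_ifn_beta1a_015,sc_ifn_beta1a,12,0
sc_ifn_beta1a_016,sc_ifn_beta1a,12,0
sc_ifn_beta1a_017,sc_ifn_beta1a,12,0
sc_ifn_beta1a_018,sc_ifn_beta1a,12,0
sc_ifn_beta1a_019,sc_ifn_beta1a,12,0
sc_ifn_beta1a_020,sc_ifn_beta1a,12,0
sc_ifn_beta1a_021,sc_ifn_beta1a,12,0
sc_ifn_beta1a_022,sc_ifn_beta1a,12,0
sc_ifn_beta1a_023,sc_ifn_beta1a,12,0
sc_ifn_beta1a_024,sc_ifn_beta1a,12,0
sc_ifn_beta1a_025,sc_ifn_beta1a,12,0
sc_ifn_beta1a_026,sc_ifn_beta1a,12,0
sc_ifn_beta1a_027,sc_ifn_beta1a,12,0
sc_ifn_beta1a_028,sc_ifn_beta1a,12,0
sc_ifn_beta1a_029,sc_ifn_beta1a,12,0
sc_ifn_beta1a_030,sc_ifn_beta1a,12,0
sc_ifn_beta1a_031,sc_ifn_beta1a,12,0
sc_ifn_beta1a_032,sc_ifn_beta1a,12,0
sc_ifn_beta1a_033,sc_ifn_beta1a,12,0
sc_ifn_beta1a_034,sc_ifn_beta1a,12,0
sc_ifn_beta1a_035,sc_ifn_beta1a,12,1
sc_ifn_beta1a_036,sc_ifn_beta1a,12,1
sc_ifn_beta1a_037,sc_ifn_beta1a,12,1
sc_ifn_beta1a_038,sc_ifn_beta1a,12,1
sc_ifn_beta1a_039,sc_ifn_beta1a,12,1
sc_ifn_beta1a_040,sc_ifn_beta1a,12,1
sc_ifn_beta1a_041,sc_ifn_beta1a,12,1
sc_ifn_beta1a_042,sc_ifn_beta1a,12,1
sc_ifn_beta1a_043,sc_ifn_beta1a,12,2
sc_ifn_beta1a_044,sc_ifn_beta1a,12,2
sc_ifn_beta1a_045,sc_ifn_beta1a,12,2
sc_ifn_beta1a_046,sc_ifn_beta1a,12,3
im_ifn_beta1a_001,im_ifn_beta1a,12,0
im_ifn_beta1a_002,im_ifn_beta1a,12,0
im_ifn_beta1a_003,im_ifn_beta1a,12,0
im_ifn_beta1a_004,im_ifn_beta1a,12,0
im_ifn_beta1a_005,im_ifn_beta1a,12,0
im_ifn_beta1a_006,im_ifn_beta1a,12,0
im_ifn_beta1a_007,im_ifn_beta1a,12,0
im_ifn_beta1a_008,im_ifn_beta1a,12,0
im_ifn_beta1a_009,im_ifn_beta1a,12,0
im_ifn_beta1a_010,im_ifn_beta1a,12,0
im_ifn_beta1a_011,im_ifn_beta1a,12,0
im_ifn_beta1a_012,im_ifn_beta1a,12,0
im_ifn_beta1a_013,im_ifn_beta1a,12,0
im_ifn_beta1a_014,im_ifn_beta1a,12,0
im_ifn_beta1a_015,im_ifn_beta1a,12,0
im_ifn_beta1a_016,im_ifn_beta1a,12,0
im_ifn_beta1a_017,im_ifn_beta1a,12,0
im_ifn_beta1a_018,im_ifn_beta1a,12,0
im_ifn_beta1a_019,im_ifn_beta1a,12,0
im_ifn_beta1a_020,im_ifn_beta1a,12,1
im_ifn_beta1a_021,im_ifn_beta1a,12,1
im_ifn_beta1a_022,im_ifn_beta1a,12,1
im_ifn_beta1a_023,im_ifn_beta1a,12,1
im_ifn_beta1a_024,im_ifn_beta1a,12,1
im_ifn_beta1a_025,im_ifn_beta1a,12,1
im_ifn_beta1a_026,im_ifn_beta1a,12,1
im_ifn_beta1a_027,im_ifn_beta1a,12,1
im_ifn_beta1a_028,im_ifn_beta1a,12,1
im_ifn_beta1a_029,im_ifn_beta1a,12,1
im_ifn_beta1a_030,im_ifn_beta1a,12,1
im_ifn_beta1a_031,im_ifn_beta1a,12,1
im_ifn_beta1a_032,im_ifn_beta1a,12,1
im_ifn_beta1a_033,im_ifn_beta1a,12,1
im_ifn_beta1a_034,im_ifn_beta1a,12,2
im_ifn_beta1a_035,im_ifn_beta1a,12,2
im_ifn_beta1a_036,im_ifn_beta1a,12,2
im_ifn_beta1a_037,im_ifn_beta1a,12,2
im_ifn_beta1a_038,im_ifn_beta1a,12,2
im_ifn_beta1a_039,im_ifn_beta1a,12,2
im_ifn_beta1a_040,im_ifn_beta1a,12,2
im_ifn_beta1a_041,im_ifn_beta1a,12,2
im_ifn_beta1a_042,im_ifn_beta1a,12,2
im_ifn_beta1a_043,im_ifn_beta1a,12,2
im_ifn_beta1a_044,im_ifn_beta1a,12,3
im_ifn_beta1a_045,im_ifn_beta1a,12,3
im_ifn_beta1a_046,im_ifn_beta1a,12,3
im_ifn_beta1a_047,im_ifn_beta1a,12,3
im_ifn_beta1a_048,im_ifn_beta1a,12,3
im_ifn_beta1a_049,im_ifn_beta1a,12,4
im_ifn_beta1a_050,im_ifn_beta1a,12,4
ga_001,ga,12,0
ga_002,ga,12,0
ga_003,ga,12,0
ga_004,ga,12,0
ga_005,ga,12,0
ga_006,ga,12,0
ga_007,ga,12,0
ga_008,ga,12,0
ga_009,ga,12,0
ga_010,ga,12,0
ga_011,ga,12,0
ga_012,ga,12,0
ga_013,ga,12,0
ga_014,ga,12,0
ga_015,ga,12,0
ga_016,ga,12,0
ga_017,ga,12,0
ga_018,ga,12,0
ga_019,ga,12,0
ga_020,ga,12,0
ga_021,ga,12,0
ga_022,ga,12,0
ga_023,ga,12,1
ga_024,ga,12,1
ga_025,ga,12,1
ga_026,ga,12,1
ga_027,ga,12,1
ga_028,ga,12,1
ga_029,ga,12,1
ga_030,ga,12,1
ga_031,ga,12,1
ga_032,ga,12,1
ga_033,ga,12,1
ga_034,ga,12,1
ga_035,ga,12,1
ga_036,ga,12,1
ga_037,ga,12,1
ga_038,ga,12,1
ga_039,ga,12,2
ga_040,ga,12,2
ga_041,ga,12,2
ga_042,ga,12,2
ga_043,ga,12,2
ga_044,ga,12,2
ga_045,ga,12,2
ga_046,ga,12,2
ga_047,ga,12,3
ga_048,ga,12,3
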
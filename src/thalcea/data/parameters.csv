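name,group,family,mean,se,units,source
discount_rate_costs,discount,fixed,0.03,,annual rate,national HTA guideline
discount_rate_outcomes,discount,fixed,0.03,,annual rate,national HTA guideline
btict_death_age_0_1,transition,beta,0.010,,probability per year,transfusion cohort literature
btict_death_age_2_5,transition,beta,0.003,,probability per year,transfusion cohort literature
btict_death_age_6_10,transition,beta,0.002,,probability per year,transfusion cohort literature
btict_death_age_11_15,transition,beta,0.010,,probability per year,transfusion cohort literature
btict_death_age_16_20,transition,beta,0.025,,probability per year,transfusion cohort literature
btict_death_age_21_30,transition,beta,0.015,,probability per year,transfusion cohort literature
btict_death_age_31_plus,transition,beta,0.345,,probability per year,transfusion cohort literature
death_constant,survival,normal_coefficient,-8.07,2.00,log baseline hazard,transplant cohort Weibull fit
death_age_coefficient,survival,normal_coefficient,0.16,0.06,per year of age at start,transplant cohort Weibull fit
death_ancillary,survival,normal_coefficient,-0.61,0.41,log Weibull shape,transplant cohort Weibull fit
failure_constant,survival,normal_coefficient,-7.18,1.55,log baseline hazard,transplant cohort Weibull fit
failure_donor_type_coefficient,survival,normal_coefficient,2.60,1.08,unrelated (1) vs related (0) donor,transplant cohort Weibull fit
failure_ancillary,survival,normal_coefficient,-0.74,0.34,log Weibull shape,transplant cohort Weibull fit
cost_related_hsct_year1,cost,gamma,491985,50288,THB per cycle,hospital database
cost_related_hsct_year2,cost,gamma,42694,15535,THB per cycle,hospital database
cost_related_hsct_following,cost,gamma,11638,3240,THB per cycle,hospital database
cost_unrelated_hsct_year1,cost,gamma,735839,183560,THB per cycle,hospital database
cost_unrelated_hsct_year2,cost,gamma,45840,20094,THB per cycle,hospital database
cost_unrelated_hsct_following,cost,gamma,6385,1037,THB per cycle,hospital database
cost_btict_annual,cost,gamma,35788,4156,THB per cycle,cost-of-illness study
cost_nonmedical_hsct_year12,cost,gamma,259994,95535,THB total over years 1-2,patient survey
cost_nonmedical_btict_annual,cost,gamma,37384,7040,THB per cycle,patient survey
cost_productivity_hsct_year12,cost,gamma,77468,70464,THB total over years 1-2,patient survey
cost_productivity_btict_annual,cost,gamma,19171,6692,THB per cycle,patient survey
utility_btict,utility,beta,0.61,0.16,utility index,meta-analysis of two studies
utility_hsct_year12,utility,beta,0.61,0.16,utility index,assumed equal to transfusion care
utility_hsct_post,utility,beta,0.93,0.05,utility index,post-transplant utility in other diseases
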
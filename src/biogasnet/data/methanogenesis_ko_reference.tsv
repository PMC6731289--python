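ko	pathway_group	BP01	BP02	BP03	BP04	BP05	BP06	BP07	BP08	BP09	BP10	BP11	BP12	BP13	BP14	BP15	BP16
K00925	acetoclastic	0.063	0.492	0.515	0.145	0.148	0.218	0.233	0.228	0.309	0.204	0.269	0.268	0.215	0.349	0.149	0.120
K00625	acetoclastic	0.015	0.632	0.630	0.090	0.189	0.097	0.083	0.077	0.546	0.040	0.244	0.106	0.054	0.448	0.078	0.031
K01895	acetoclastic	5.218	0.155	0.061	0.056	4.268	0.116	0.071	0.062	0.056	0.118	0.066	0.077	0.092	0.977	0.105	0.043
K00193	acetoclastic	1.622	3.578	3.325	0.165	2.574	0.434	0.310	0.255	1.783	0.275	1.961	0.705	0.314	3.146	0.201	0.099
K00197	acetoclastic	1.673	3.862	3.516	0.537	2.344	0.824	0.861	0.788	2.049	0.437	1.690	0.829	0.951	2.890	1.219	0.229
K00194	acetoclastic	0.794	1.091	1.083	0.332	0.889	0.414	0.475	0.434	0.491	0.223	0.526	0.409	0.440	0.892	0.528	0.100
K00577	shared	0.624	0.610	0.718	0.350	0.576	0.521	0.486	0.483	0.500	0.405	0.530	0.566	0.451	0.528	0.239	0.237
K00578	shared	0.003	0.021	0.019	0.000	0.006	0.002	0.003	0.003	0.011	0.004	0.013	0.004	0.002	0.014	0.007	0.001
K00579	shared	0.004	0.003	0.001	0.007	0.002	0.000	0.000	0.001	0.000	0.001	0.000	0.000	0.000	0.000	0.000	0.004
K00580	shared	0.040	0.005	0.013	0.068	0.023	0.063	0.053	0.046	0.018	0.052	0.027	0.084	0.067	0.016	0.024	0.032
K00581	shared	0.150	0.176	0.171	0.185	0.146	0.260	0.196	0.204	0.149	0.220	0.188	0.344	0.275	0.142	0.122	0.097
K00582	shared	0.000	0.001	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.001	0.000	0.000
K00583	shared	0.000	0.008	0.005	0.000	0.004	0.000	0.000	0.000	0.008	0.000	0.007	0.000	0.001	0.007	0.002	0.000
K00584	shared	0.633	1.209	1.470	0.299	0.713	0.246	0.245	0.260	1.002	0.222	0.841	0.394	0.233	1.086	0.229	0.199
K00200	hydrogenotrophic	0.047	0.035	0.033	0.371	0.027	0.184	0.092	0.069	0.056	0.089	0.131	0.174	0.114	0.040	0.075	0.284
K00201	hydrogenotrophic	0.095	0.137	0.150	0.444	0.107	0.289	0.308	0.280	0.166	0.250	0.246	0.338	0.250	0.142	0.077	0.444
K00202	hydrogenotrophic	0.042	0.022	0.030	0.104	0.022	0.061	0.085	0.075	0.027	0.071	0.059	0.085	0.079	0.025	0.014	0.157
K00203	hydrogenotrophic	0.002	0.010	0.008	0.071	0.003	0.053	0.062	0.060	0.022	0.065	0.047	0.073	0.056	0.021	0.035	0.077
K11261	hydrogenotrophic	0.026	0.131	0.089	0.135	0.057	0.485	0.340	0.293	0.297	0.324	0.270	0.281	0.439	0.132	0.090	0.140
K00205	hydrogenotrophic	0.009	0.003	0.007	0.170	0.033	0.074	0.067	0.060	0.046	0.051	0.066	0.097	0.069	0.020	0.021	0.092
K00672	hydrogenotrophic	0.048	0.021	0.023	0.132	0.035	0.129	0.169	0.159	0.050	0.108	0.070	0.136	0.096	0.034	0.030	0.318
K01499	hydrogenotrophic	0.004	0.020	0.022	0.145	0.011	0.047	0.067	0.050	0.021	0.052	0.054	0.081	0.032	0.026	0.015	0.074
K00319	hydrogenotrophic	0.716	0.225	0.461	3.794	0.780	3.147	3.450	3.783	1.296	2.968	1.427	3.019	3.261	0.811	0.911	4.184
K13942	hydrogenotrophic	0.002	0.001	0.001	0.007	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.005	0.000
K00320	hydrogenotrophic	1.773	0.658	1.008	7.922	1.525	5.384	5.908	6.070	2.424	5.034	3.152	7.065	5.372	1.389	2.679	7.457
K00399	common	6.625	12.755	13.288	4.747	8.172	8.010	6.397	6.470	8.533	4.739	9.775	4.849	6.355	11.437	3.222	3.292
K00401	common	5.649	6.689	6.593	6.703	4.780	8.002	6.508	6.344	5.438	4.384	5.988	4.731	5.717	5.882	1.755	4.351
K00402	common	7.039	13.444	13.935	4.923	7.129	6.186	5.383	5.367	9.987	3.885	10.420	4.618	4.731	11.247	2.532	2.708
K03388	common	0.079	0.051	0.074	0.917	0.109	0.604	0.546	0.543	0.208	0.647	0.361	0.594	0.577	0.215	0.602	0.573
K03389	common	0.009	0.005	0.011	0.146	0.007	0.050	0.047	0.042	0.013	0.050	0.040	0.072	0.047	0.015	0.027	0.075
K03390	common	0.006	0.003	0.007	0.074	0.005	0.030	0.024	0.024	0.007	0.035	0.028	0.042	0.032	0.006	0.021	0.045
K08264	common	0.213	0.157	0.232	0.004	0.180	0.003	0.002	0.002	0.123	0.001	0.096	0.032	0.018	0.142	0.022	0.001
K08265	common	0.000	0.002	0.002	0.000	0.000	0.000	0.000	0.000	0.001	0.000	0.002	0.000	0.000	0.002	0.000	0.000
K14126	common	0.004	0.009	0.015	0.048	0.035	0.035	0.037	0.044	0.025	0.021	0.018	0.022	0.018	0.023	0.025	0.028
K14127	common	0.002	0.003	0.006	0.005	0.011	0.000	0.000	0.000	0.000	0.000	0.001	0.001	0.000	0.002	0.000	0.000
K22516	common	0.558	0.153	0.301	1.524	0.431	0.392	0.660	0.663	0.248	0.474	0.425	0.665	0.538	0.263	0.355	2.457
K00125	common	0.099	0.045	0.080	0.480	0.067	0.110	0.147	0.140	0.045	0.095	0.095	0.152	0.098	0.057	0.136	0.653
K14080	methylotrophic	0.000	0.019	0.022	0.000	0.006	0.000	0.000	0.000	0.021	0.000	0.016	0.000	0.001	0.016	0.001	0.000
K04480	methylotrophic	0.326	1.167	0.512	0.079	0.609	0.019	0.176	0.172	1.019	0.023	0.498	0.116	0.067	1.440	0.104	0.042
K14081	methylotrophic	0.045	0.298	0.124	0.006	0.146	0.015	0.026	0.024	0.249	0.007	0.139	0.031	0.014	0.361	0.024	0.007
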
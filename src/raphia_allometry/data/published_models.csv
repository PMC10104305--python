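model_id,predictors,a,b,c,d,R2adj,RSE,AIC,RMSE,BiasPct,CF,subset,n,best_single,best_multiple
m1,SDp,-2.496,1.727,,,0.97,0.21,-19.48,15.44,0.02,1.02,2-15 cm,90,True,False
m2,D,-6.308,3.211,,,0.86,0.44,113.53,39.28,-4.58,1.10,2-15 cm,90,False,False
m3,MDp,-1.777,2.993,,,0.92,0.35,69.60,28.77,-5.59,1.06,2-15 cm,90,False,False
m4,H,-5.262,3.404,,,0.82,0.50,136.13,38.51,-5.55,1.13,2-15 cm,90,False,False
m5,Npf,-1.837,3.108,,,0.79,0.55,151.96,37.73,8.61,1.16,2-15 cm,90,False,False
m6,TD,7.792,3.206,,,0.07,1.15,285.26,66.88,8.78,1.94,2-15 cm,90,False,False
m7,SDp+H,-3.318,1.431,0.721,,0.98,0.18,-46.25,15.37,-1.54,1.02,2-15 cm,90,False,False
m8,SDp+Npf,-2.431,2.087,-0.769,,0.97,0.19,-37.86,15.97,-2.01,1.02,2-15 cm,90,False,False
m9,SDp+TD,-1.751,1.707,0.493,,0.97,0.21,-23.09,15.93,0.22,1.02,2-15 cm,90,False,False
m10,SDp+H+Npf,-3.084,1.683,0.544,-0.383,0.98,0.18,-48.54,15.45,-2.19,1.02,2-15 cm,90,False,False
m11,SDp+H+TD,-2.691,1.425,0.695,0.395,0.98,0.18,-49.15,15.71,-1.55,1.02,2-15 cm,90,False,True
m12,SDp,-2.238,1.662,,,0.94,0.19,-24.05,19.95,-1.67,1.02,5-15 cm,60,False,False
m13,D,-5.737,3.048,,,0.69,0.45,77.3,48.07,-3.76,1.11,5-15 cm,60,False,False
m14,MDp,-2.573,3.400,,,0.77,0.39,59.84,33.89,-5.59,1.08,5-15 cm,60,False,False
m15,H,-5.027,3.349,,,0.64,0.48,86.29,45.59,0.27,1.12,5-15 cm,60,False,False
m16,Npf,-0.272,2.353,,,0.80,0.36,50.73,41.86,-2.59,1.07,5-15 cm,60,False,False
m17,TD,6.075,1.497,,,0.03,0.79,145.41,72.19,-1.24,1.37,5-15 cm,60,False,False
m18,SDp+H,-3.370,1.44,0.729,,0.96,0.17,-38.32,18.41,-1.25,1.01,5-15 cm,60,False,False
m19,SDp+Npf,-2.478,1.964,-0.491,,0.95,0.19,-26.25,18.69,-1.16,1.02,5-15 cm,60,False,False
m20,SDp+TD,-1.920,1.653,0.209,,0.94,0.19,-22.89,19.99,-1.56,1.02,5-15 cm,60,False,False
m21,SDp+H+Npf,-3.375,1.559,0.678,-0.169,0.95,0.17,-36.87,18.06,-1.43,1.01,5-15 cm,60,False,False
m22,SDp+H+TD,-3.232,1.440,0.718,0.080,0.95,0.17,-36.00,18.44,-1.24,1.01,5-15 cm,60,False,False
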
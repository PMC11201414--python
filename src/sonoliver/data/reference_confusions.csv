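feature,classifier,tp,tn,fp,fn,mse,exp_accuracy,exp_f1,exp_mcc,exp_f_measure,exp_error_rate,exp_jaccard
pcm,gmm,509,531,398,421,1.09e-4,55.95,55.42,0.12,0.55,44.05,38.33
pcm,sdc,576,597,332,354,5.19e-5,63.10,62.65,0.26,0.63,36.90,45.61
pcm,hs,642,509,420,288,1.17e-4,61.90,64.44,0.24,0.65,38.10,47.54
pcm,svm-linear,509,465,464,421,3.33e-4,52.38,53.49,0.05,0.54,47.62,36.51
pcm,svm-poly,531,597,332,399,7.38e-5,60.71,59.26,0.21,0.59,39.29,42.11
pcm,svm-rbf,700,640,289,160,2.53e-5,74.90,75.72,0.51,0.76,25.10,60.92
pcm,aao,772,641,288,158,2.31e-5,76.01,77.59,0.53,0.78,23.99,63.38
pcm,aao-gmm,797,619,310,133,2.22e-5,76.19,78.26,0.53,0.79,23.81,64.29
fcm,gmm,619,752,177,311,3.0e-5,73.81,71.79,0.48,0.72,26.19,56.00
fcm,sdc,664,575,354,266,4.09e-5,66.67,68.18,0.33,0.68,33.33,51.72
fcm,hs,774,663,266,156,1.62e-5,77.38,78.65,0.55,0.79,22.62,64.81
fcm,svm-linear,907,486,443,23,2.01e-4,75.00,79.61,0.56,0.81,25.00,66.13
fcm,svm-poly,752,752,177,178,1.22e-5,80.95,80.95,0.62,0.81,19.05,68.00
fcm,svm-rbf,818,796,133,112,4.57e-6,86.90,87.06,0.74,0.87,13.10,77.08
fcm,aao,870,860,69,60,1.22e-6,91.67,91.76,0.83,0.92,8.33,84.78
fcm,aao-gmm,841,840,89,89,1.39e-6,90.48,90.48,0.81,0.90,9.52,82.61
pfcm,gmm,819,885,44,111,2.05e-6,91.67,91.36,0.84,0.91,8.33,84.09
pfcm,sdc,554,774,155,377,3.701e-5,71.43,67.57,0.44,0.68,28.57,51.02
pfcm,hs,819,686,243,111,1.249e-5,80.95,82.22,0.63,0.82,19.05,69.81
pfcm,svm-linear,797,708,221,133,1.306e-5,80.95,81.82,0.62,0.82,19.05,69.23
pfcm,svm-poly,797,752,177,133,8.54e-6,83.33,83.72,0.67,0.84,16.67,72.00
pfcm,svm-rbf,841,796,133,89,3.145e-6,88.10,88.37,0.76,0.88,11.90,79.17
pfcm,aao,863,774,155,67,5.125e-6,88.10,88.64,0.77,0.89,11.90,79.59
pfcm,aao-gmm,886,885,44,44,2.6e-7,99.03,95.24,0.90,0.95,0.97,90.91
sampen,gmm,686,818,111,244,1.331e-5,80.95,79.49,0.63,0.80,19.05,65.96
sampen,sdc,753,774,155,177,1.265e-5,82.14,81.93,0.64,0.82,17.86,69.39
sampen,hs,664,553,376,266,4.42e-5,65.48,67.42,0.31,0.68,34.52,50.85
sampen,svm-linear,664,531,398,266,5.545e-5,64.29,66.67,0.29,0.67,35.71,50.00
sampen,svm-poly,797,664,265,133,1.702e-5,78.57,80.00,0.58,0.80,21.43,66.67
sampen,svm-rbf,841,818,111,89,1.945e-6,89.29,89.41,0.79,0.89,10.71,80.85
sampen,aao,886,863,66,44,6.5e-7,94.05,94.12,0.88,0.94,5.95,88.89
sampen,aao-gmm,819,841,88,111,2.745e-6,89.29,89.16,0.79,0.89,10.71,80.43
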
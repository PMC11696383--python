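# packaged per-character response profiles (amplitude in mV, period in s)
label,amp_q1,amp_q2,amp_q3,amp_mean,amp_max,amp_min,amp_sd,per_q1,per_q2,per_q3,per_mean,per_max,per_min,per_sd
A,2.09,2.49,3.13,2.65,5.46,1.81,0.72,677.75,847.00,1873.75,2034.88,14558.00,667.00,2613.48
B,2.39,2.73,3.35,2.98,5.76,2.12,0.81,677.25,838.00,1308.00,1991.27,23894.00,667.00,3220.38
C,2.54,3.48,4.78,3.97,10.09,2.09,1.88,698.50,863.00,2834.35,2320.62,12370.00,668.00,2876.84
D,13.23,15.63,20.65,17.26,42.73,7.54,6.75,10296.75,11064.00,12970.00,11755.72,18677.00,1646.00,2764.74
E,4.66,7.99,12.29,8.71,19.69,2.63,4.67,6790.25,8029.00,10092.75,8840.02,19481.00,3453.00,2550.49
F,2.63,3.50,5.02,4.96,28.42,1.82,4.93,1760.75,1956.00,2456.75,2375.00,7749.00,1640.00,1201.26
G,5.25,8.06,12.62,9.48,28.62,3.26,5.34,6854.25,7968.00,10115.25,8667.16,14989.00,3543.00,2189.26
H,10.49,14.73,19.01,15.62,41.07,5.19,7.39,10278.50,10983.50,10923.00,11816.00,19855.00,1646.00,2863.47
I,4.84,6.63,10.22,7.67,16.88,3.56,3.58,6750.50,8211.50,10101.00,8486.91,13328.00,479.00,2222.62
J,3.22,4.24,5.47,4.67,9.83,2.14,1.91,1713.25,1895.00,2600.25,2188.31,3939.00,1667.00,644.62
K,3.23,5.10,7.11,5.22,14.18,1.57,2.44,706.00,811.00,1058.00,994.85,7756.00,557.00,814.62
L,13.80,16.66,19.83,16.95,23.96,9.85,3.58,7091.00,8228.00,10715.00,8791.55,13290.00,1013.00,2152.00
M,3.81,5.15,6.68,5.52,10.70,3.25,1.97,1789.00,2201.00,2850.50,2644.84,11105.00,1672.00,1613.56
N,3.48,6.33,9.30,6.64,17.80,1.93,3.27,1708.25,1924.00,2606.75,2410.44,10225.00,1667.00,1242.14
O,2.58,3.40,4.20,3.76,10.77,1.56,1.85,708.75,800.00,1036.25,916.48,2143.00,430.00,297.24
P,4.36,7.90,12.38,8.73,20.57,2.47,4.77,6901.00,8304.00,10927.25,9059.41,15742.00,3543.00,2435.82
Q,5.79,7.10,10.07,7.88,18.47,2.63,2.79,7049.00,8422.00,10388.50,8782.50,14201.00,2501.00,2042.21
R,2.45,3.32,4.59,3.71,10.12,1.93,1.57,676.50,764.00,1168.25,1698.31,13440.00,667.00,2369.86
S,9.84,13.14,16.24,13.25,20.78,6.17,3.70,7266.25,8231.00,9891.00,8673.19,13286.00,1013.00,1017.16
T,6.44,7.87,10.69,8.67,17.04,3.47,2.98,6901.00,7937.50,10175.00,8578.50,13294.00,2501.00,1997.67
U,8.91,10.88,14.70,11.86,21.92,6.46,3.89,6946.00,8014.00,9958.25,8648.24,13346.00,6667.00,1916.67
V,5.48,8.53,10.51,8.13,16.22,2.20,3.38,7571.00,8659.00,10341.00,8984.98,13045.00,10.00,2790.96
W,7.04,9.44,12.27,9.71,16.94,4.22,3.42,7232.00,9033.00,10796.00,9385.23,20174.00,6151.00,2558.68
X,6.43,7.80,10.08,8.29,14.23,3.69,2.54,7040.50,8070.00,10053.25,8679.42,13294.00,2501.00,2039.60
Y,1.93,2.59,4.26,3.30,7.79,1.83,1.77,699.00,928.00,2653.50,2342.25,9873.00,20.00,2872.05
Z,2.08,2.94,12.91,7.17,29.45,1.84,7.72,723.25,904.00,1262.75,1473.15,6495.00,197.00,1540.10
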
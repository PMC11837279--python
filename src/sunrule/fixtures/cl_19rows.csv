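MQ8,MQ3,NH3,T2602,NO2,T822,HCHO,T2620,MS1100,MQ7,MQ6,MQ4,MQ135,TEMP1,NEM1,Class
275.2,590.9,513.6,937.8,51.7,893.3,186.2,961,348.6,165.5,348.9,139.6,935.1,32,27.2,Y
216,539.2,594.8,932.4,98.8,843,232.4,963.2,220.5,137,283.8,110.8,930,34.8,27.4,V
198.7,519.1,647.3,927.8,77.7,837.3,162,962.8,209,129,269.9,104.6,930,36,24.9,V
198.5,511.1,600,928.4,77.4,862,137.4,963,206.4,130.3,270,109.4,931.4,38,26,Y
192.09,498.18,610.91,923.45,70.55,853.55,121.55,960,199.36,126.91,264.45,106,931.55,39,24.45,V
187.82,486.73,622.09,923.36,69.18,842.36,112.45,956,193.45,125.45,260.73,104.09,931.09,40,23,V
187.27,482.09,631.64,920.09,69.55,836.91,108.73,951.36,190,124.18,259.45,102,930.09,41,22.09,V
236.6,507.7,772.8,942.6,260.4,779.6,197.4,922.8,453.6,239.2,287.3,333.3,926.9,31,24,Y
262.5,525.7,769.2,941.2,230.5,781.2,127.7,896.1,421.3,251,321.8,251,927,30,25.8,Y
266.9,525.4,777,940,227.7,697,134.9,889,410.5,251,327.1,240.8,927.8,30.8,27.4,Y
273.7,527.4,778.3,935.9,225.4,761.1,119.6,882.5,402.6,250.6,334.7,227.8,924.5,31,29,V
282,531.4,771.6,935.7,218.2,771.3,124.9,875.6,394.7,252,343.7,224,925.6,31,29.2,Y
287,532.36,769.82,934.09,214.55,762.64,125.18,869.36,388.55,251.64,348.27,218.27,925.82,31.27,29,V
294.7,536.1,760.2,933.1,211.6,722.3,122,865.6,383.9,252,355.5,212.3,926.8,32,29.6,V
252.82,573.18,537.18,933.36,53,887,133.36,955.09,278.45,159.91,328.64,129.73,900,33,31,V
207.2,530.7,626.3,912.1,60.4,841.6,101.8,950,204.2,136.5,277.4,104.9,861.9,34,28.3,Y
192,510.1,631.3,910.6,61.7,842.9,90.3,947,184,130.5,262,102,864.9,35,29.2,V
180.8,490.6,651.8,911.4,62.1,830,87.7,945.1,175,123.8,252.6,96.2,886.8,36,27.7,V
177.3,479.8,653.7,910.3,63,827.4,86,944.6,170,119.7,249.3,93.4,873.5,36.2,27,V
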